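"""Run the whole pipeline end to end and print the cohort summary.

Equivalent to `thyroclass run --synthetic --seed 1 --out thyroclass_out`,
with reduced bootstrap counts for a quick demonstration.
"""

import json

import thyroclass as tc

config = tc.PipelineConfig(seed=1, hopkins_reps=128, consensus_reps=50)
summary = tc.run_pipeline(config, "thyroclass_out")
print(json.dumps(summary, indent=2, sort_keys=True))

# The summary aggregates every stage: record counts through the filters,
# clusterability (mean 1-H), the consensus k with its vote table, outliers,
# group sizes after BL/RL assignment of driver-negative samples, and
# per-group mean TMB and fusion burden. Full per-sample tables are in
# thyroclass_out/.
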