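"""Simulate a synthetic thyroid-tumor cohort with known ground truth.

Builds the default 30-sample cohort — two expression archetypes (BRAF-like,
RAS-like), planted driver lesions, stratified background variant calls and
Poisson fusion calls — and prints its composition.
"""

from collections import Counter

import thyroclass as tc

config = tc.CohortConfig(seed=1)
counts, truth = tc.generate_counts(config)
variants = tc.generate_variant_table(config, truth)
fusions = tc.generate_fusion_table(config, truth)

print(f"count matrix: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
print("archetypes:", dict(Counter(truth.archetype.values())))
print("driver status:", dict(Counter(truth.driver_status.values())))
print(f"variant calls: {len(variants)} ({len(truth.planted_variants)} planted drivers)")
print(f"fusion calls: {len(fusions)} ({len(truth.planted_fusions)} planted PAX8--PPARG)")

# The archetype split drives everything downstream: clustering should find
# these two groups, and driver-negative samples should inherit the group of
# the mutation-positive tumors they cluster with.
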