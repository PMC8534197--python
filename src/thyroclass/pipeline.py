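"""End-to-end orchestration: generate or ingest, filter, cluster, score, report.

``run_pipeline`` wires the stages together: variant filter chain, fusion
filters, expression-matrix construction, clusterability + consensus-k +
WPGMA clustering with PCA and outlier flagging, BL/RL assignment of
driver-negative samples, and the BRS/TDS/ERK/TMB score panel. It writes a
fixed set of report files (variant audit, fusion audit, expression matrix,
cluster report, score panel, JSON summary), each stamped with a fingerprint
of the resolved configuration. Every stage logs its record counts; nothing
is dropped silently.

Samples flagged as expression outliers are excluded from clustering and
from group summaries but still receive scores.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, expression, fusions, scores, synthetic, variants
from .synthetic import CohortConfig
from .exceptions import ValidationError

logger = logging.getLogger("thyroclass")

POSITIVE_GROUPS = {
    "positive-BRAF": "BRAF-positive",
    "positive-RAS": "RAS/PAX8-PPARg-positive",
    "positive-PAX8-PPARg": "RAS/PAX8-PPARg-positive",
}


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults, plus input paths.

    In synthetic mode the cohort is generated from ``cohort`` and no input
    paths are needed; otherwise paths to the variant MAF, fusion TSV, count
    matrix, sample annotation, reference matrix and labels must resolve.
    """

    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # input paths (non-synthetic mode)
    variants_path: str | None = None
    fusions_path: str | None = None
    counts_path: str | None = None
    annotations_path: str | None = None  # sample_id, driver_status, histology
    reference_path: str | None = None
    reference_labels_path: str | None = None
    normal_variants_path: str | None = None
    fusion_blacklist_path: str | None = None
    brs_signature_path: str | None = None
    tds_signature_path: str | None = None
    erk_signature_path: str | None = None
    # stage parameters (defaults follow the published filter chain)
    min_qc: float = 20.0
    max_af: float = 0.001
    min_ffpm: float = 0.1
    min_support: int = 10
    support_mode: str = "each"
    min_count: int = 10
    min_fraction: float = 0.9
    hopkins_reps: int = 512
    consensus_reps: int = 1080
    gene_fraction: float = 0.1
    k_max: int = 8
    z_outlier: float = 3.0
    capture_size_mb: float = 50.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["archetype_fractions"] = dict(d["cohort"]["archetype_fractions"])
        d["cohort"]["fusion_rate_by_archetype"] = dict(d["cohort"]["fusion_rate_by_archetype"])
        d["cohort"]["library_size_range"] = list(d["cohort"]["library_size_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = dict(cohort)
            if "library_size_range" in cohort:
                cohort["library_size_range"] = tuple(cohort["library_size_range"])
            cohort = CohortConfig(**cohort)
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, fingerprint: str, index: bool = False,
               index_label: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config={fingerprint}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label,
                  float_format="%.6g", lineterminator="\n")


def _load_inputs(config: PipelineConfig):
    """Resolve cohort inputs either from the generator or from files."""
    if config.synthetic:
        cohort = replace(config.cohort, seed=config.seed)
        counts, truth = synthetic.generate_counts(cohort)
        var_records = synthetic.generate_variant_table(cohort, truth)
        fus_records = synthetic.generate_fusion_table(cohort, truth)
        normal = variants.NormalVariantSet(synthetic.normal_variant_keys(var_records))
        blacklist = synthetic.normal_fusion_blacklist()
        ref_expr, ref_labels = synthetic.generate_reference_matrix(cohort)
        sig = synthetic.signature_genes(cohort)
        signatures = {
            "BRS": scores.GeneSignature("BRS", sig["BRS"]),
            "TDS": scores.GeneSignature("TDS", sig["TDS"]),
            "ERK": scores.GeneSignature("ERK", sig["ERK"]),
        }
        driver_status = truth.driver_status
        histology = {}
    else:
        for name in ("variants_path", "fusions_path", "counts_path", "annotations_path",
                     "reference_path", "reference_labels_path",
                     "brs_signature_path", "tds_signature_path", "erk_signature_path"):
            if getattr(config, name) is None:
                raise ValidationError(f"non-synthetic mode requires {name}")
        counts = expression.read_counts_tsv(config.counts_path)
        var_records = variants.read_maf(config.variants_path)
        fus_records = fusions.read_fusion_tsv(config.fusions_path)
        normal = (variants.NormalVariantSet.from_tsv(config.normal_variants_path)
                  if config.normal_variants_path else variants.NormalVariantSet())
        if config.fusion_blacklist_path:
            bl = pd.read_csv(config.fusion_blacklist_path, sep="\t", header=None)
            blacklist = {(str(a), str(b)) for a, b in zip(bl[0], bl[1])}
        else:
            blacklist = set()
        ref_fpm = expression.read_expression_tsv(config.reference_path)
        ref_expr = expression.ExpressionMatrix(
            values=ref_fpm, size_factors=pd.Series(1.0, index=ref_fpm.columns), logged=False
        )
        lab = pd.read_csv(config.reference_labels_path, sep="\t", index_col=0)
        ref_labels = lab.iloc[:, 0]
        ann = pd.read_csv(config.annotations_path, sep="\t", index_col=0)
        driver_status = ann["driver_status"].to_dict()
        histology = ann["histology"].to_dict() if "histology" in ann.columns else {}
        signatures = {
            "BRS": scores.read_signature(config.brs_signature_path, "BRS"),
            "TDS": scores.read_signature(config.tds_signature_path, "TDS"),
            "ERK": scores.read_signature(config.erk_signature_path, "ERK"),
        }
    return (counts, var_records, fus_records, normal, blacklist,
            ref_expr, ref_labels, signatures, driver_status, histology)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the cohort report into ``out_dir``.

    Returns the JSON-ready summary dictionary (also written to
    ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fp = config.fingerprint()
    (counts, var_records, fus_records, normal, blacklist,
     ref_expr, ref_labels, signatures, driver_status, histology) = _load_inputs(config)
    samples = list(counts.samples)
    logger.info("inputs: %d samples, %d genes, %d variant calls, %d fusion calls",
                len(samples), counts.counts.shape[0], len(var_records), len(fus_records))

    # --- variants
    retained, audit = variants.run_variant_filter_chain(
        var_records, normal, min_qc=config.min_qc, max_af=config.max_af
    )
    logger.info("variant filter: %d in -> %d retained", len(var_records), len(retained))
    _write_tsv(audit, out / "variant_audit.tsv", fp)

    # --- fusions
    fus = fusions.filter_fusions(
        fus_records, min_ffpm=config.min_ffpm,
        min_support=config.min_support, support_mode=config.support_mode,
    )
    fus = fusions.subtract_normal_fusions(fus, blacklist)
    n_pass_fus = sum(r.status == "pass" for r in fus)
    logger.info("fusion filter: %d in -> %d passing", len(fus), n_pass_fus)
    fusions.write_fusion_tsv(fus, out / "fusion_audit.tsv", with_status=True)

    # --- expression
    log_expr = expression.build_expression_matrix(
        counts, min_count=config.min_count, min_fraction=config.min_fraction, log=True
    )
    fpm = expression.build_expression_matrix(
        counts, min_count=config.min_count, min_fraction=config.min_fraction, log=False
    ).values
    logger.info("expression matrix: %d of %d genes retained",
                log_expr.values.shape[0], counts.counts.shape[0])
    expression.write_expression_tsv(log_expr.values, out / "expression_matrix.tsv",
                                    header=f"config={fp}")

    # --- clustering
    outliers = clustering.flag_outliers(log_expr.values, z_threshold=config.z_outlier)
    clustered_matrix = log_expr.values.drop(columns=sorted(outliers))
    hopkins_mean, clusterable = clustering.bootstrapped_clusterability(
        clustered_matrix, reps=config.hopkins_reps, seed=config.seed
    )
    consensus = clustering.consensus_cluster_number(
        clustered_matrix, k_range=range(2, config.k_max + 1),
        reps=config.consensus_reps, gene_fraction=config.gene_fraction, seed=config.seed,
    )
    _, labels = clustering.wpgma_cluster(clustered_matrix, consensus.chosen_k)
    coords = clustering.pca_project(log_expr.values, n_components=2)
    assignments = clustering.assign_negative_classes(labels, driver_status, histology)
    logger.info("clustering: mean 1-H=%.3f, k=%d, %d outliers",
                hopkins_mean, consensus.chosen_k, len(outliers))

    report = pd.DataFrame({
        "sample_id": samples,
        "cluster": [labels.get(s, -1) for s in samples],
        "assignment": [
            assignments.get(s, POSITIVE_GROUPS.get(driver_status.get(s, ""), ""))
            for s in samples
        ],
        "PC1": coords.loc[samples, "PC1"].to_numpy(),
        "PC2": coords.loc[samples, "PC2"].to_numpy(),
        "outlier": [int(s in outliers) for s in samples],
    })
    _write_tsv(report, out / "cluster_report.tsv", fp)

    # --- scores (outliers still scored)
    centroids = scores.fit_centroids(ref_expr.values, ref_labels, signatures["BRS"])
    var_counts = scores.nonsynonymous_counts(retained, samples)
    panel = scores.score_panel(
        fpm, centroids, signatures["TDS"], signatures["ERK"],
        var_counts, capture_size_mb=config.capture_size_mb,
    )
    _write_tsv(panel, out / "score_panel.tsv", fp, index=True, index_label="sample_id")
    logger.info("score panel: %d samples scored", panel.shape[0])

    # --- group summaries (outliers excluded)
    groups = {
        s: assignments.get(s, POSITIVE_GROUPS.get(driver_status.get(s, ""), "other"))
        for s in samples if s not in outliers
    }
    fusion_burden = fusions.fusion_burden(
        [r for r in fus if r.sample_id in groups], groups
    )
    summary_table = summarize_groups(panel, groups, fus)
    _write_tsv(summary_table, out / "group_summary.tsv", fp, index=True, index_label="group")

    summary = {
        "config_fingerprint": fp,
        "n_samples": len(samples),
        "n_variants_in": len(var_records),
        "n_variants_retained": len(retained),
        "n_fusions_in": len(fus),
        "n_fusions_passing": n_pass_fus,
        "hopkins_mean": hopkins_mean,
        "clusterable": bool(clusterable),
        "per_k_votes": {str(k): v for k, v in consensus.per_k_votes.items()},
        "chosen_k": consensus.chosen_k,
        "outliers": sorted(outliers),
        "group_sizes": {g: int((pd.Series(groups) == g).sum()) for g in sorted(set(groups.values()))},
        "group_mean_tmb": {
            g: float(panel.loc[[s for s, gg in groups.items() if gg == g], "TMB"].mean())
            for g in sorted(set(groups.values()))
        },
        "group_fusion_burden": fusion_burden,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def summarize_groups(
    panel: pd.DataFrame,
    groups: dict[str, str],
    fusion_records=(),
) -> pd.DataFrame:
    """Per-group n, mean TMB, mean fusion burden and mean BRS/TDS/ERK.

    Groups with no member are reported with n = 0 and missing means.
    """
    fus_counts = fusions.passing_counts(fusion_records, groups.keys()) if groups else {}
    rows = {}
    for g in sorted(set(groups.values())):
        members = [s for s, gg in groups.items() if gg == g and s in panel.index]
        if not members:
            rows[g] = {"n": 0, "mean_TMB": np.nan, "mean_fusions": np.nan,
                       "mean_BRS": np.nan, "mean_TDS": np.nan, "mean_ERK": np.nan}
            continue
        sub = panel.loc[members]
        rows[g] = {
            "n": len(members),
            "mean_TMB": float(sub["TMB"].mean()),
            "mean_fusions": float(np.mean([fus_counts.get(s, 0) for s in members])),
            "mean_BRS": float(sub["BRS"].mean()),
            "mean_TDS": float(sub["TDS"].mean()),
            "mean_ERK": float(sub["ERK"].mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
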