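"""Per-sample score panel: BRS, TDS, ERK score and tumor mutation burden.

The BRAF-RAS score (BRS) places each tumor on a continuum between the two
canonical thyroid-cancer expression programs. Centroids of BRAF V600E- and
RAS-mutant reference samples are fitted on the FPM expression of a 71-gene
signature; each scored sample's raw score is the difference of its Euclidean
distances to the two centroids, and the cohort is rescaled so scores span
[-1, 1]. Negative BRS means BRAF-like, positive means RAS-like.

The Thyroid Differentiation Score (TDS, 16 thyroid-function genes) and ERK
score (52 MAPK-pathway genes) are means of median-centered log2 expression:
per gene, log2(FPM + 1) values are centered by the gene's cohort median,
then averaged over the signature per sample. Lower TDS = less
differentiated; higher ERK = more MAPK output.

TMB is the count of retained non-synonymous somatic mutations (silent calls
excluded) divided by the capture size in megabases (default 50 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .variants import VariantRecord


@dataclass
class GeneSignature:
    """Named, ordered gene list (default sizes: BRS 71, TDS 16, ERK 52)."""

    name: str
    genes: list[str]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")


@dataclass
class ReferenceCentroids:
    """Mean FPM profiles of the BRAF- and RAS-mutant reference groups."""

    genes: list[str]
    centroid_braf: np.ndarray
    centroid_ras: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.centroid_braf).all() and np.isfinite(self.centroid_ras).all()):
            raise ValidationError("centroids contain non-finite values")


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a one-gene-per-line signature file (e.g. brs71.txt)."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneSignature(name=name or path.stem, genes=genes)


def _signature_submatrix(matrix: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"signature genes missing from matrix: {missing}")
    return matrix.loc[list(genes)]


def fit_centroids(
    reference_matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    signature: GeneSignature,
    braf_label: str = "BRAF V600E",
    ras_label: str = "RAS",
) -> ReferenceCentroids:
    """Fit the BRAF and RAS centroids on signature-gene FPM profiles.

    Within each labelled group the centroid is the k-means solution with a
    single cluster, i.e. the group mean vector (group membership is already
    fixed by mutation status, so within-group clustering is degenerate).
    """
    labels = pd.Series(labels)
    sub = _signature_submatrix(reference_matrix, signature.genes)
    centroids = {}
    for name in (braf_label, ras_label):
        members = labels.index[labels == name]
        members = [s for s in members if s in sub.columns]
        if not members:
            raise ValidationError(f"no reference samples labelled {name!r}")
        centroids[name] = sub[members].to_numpy(dtype=float).mean(axis=1)
    return ReferenceCentroids(
        genes=list(signature.genes),
        centroid_braf=centroids[braf_label],
        centroid_ras=centroids[ras_label],
    )


def brs_score(samples_matrix: pd.DataFrame, centroids: ReferenceCentroids) -> pd.Series:
    """BRAF-RAS score per sample, scaled to [-1, 1] over the scored cohort.

    raw_i = d(x_i, centroid_BRAF) - d(x_i, centroid_RAS) on signature-gene
    FPM profiles, then divided by the cohort maximum |raw|. At least one
    sample sits at -1 or +1 unless every raw score is zero (then all scores
    are 0). Negative = BRAF-like.
    """
    if samples_matrix.shape[1] == 0:
        raise ValidationError("cannot score an empty cohort")
    sub = _signature_submatrix(samples_matrix, centroids.genes).to_numpy(dtype=float)
    d_braf = np.linalg.norm(sub - centroids.centroid_braf[:, None], axis=0)
    d_ras = np.linalg.norm(sub - centroids.centroid_ras[:, None], axis=0)
    raw = d_braf - d_ras
    scale = np.abs(raw).max()
    scores = raw / scale if scale > 0 else np.zeros_like(raw)
    return pd.Series(scores, index=samples_matrix.columns, name="BRS")


def _median_centered_log_mean(matrix: pd.DataFrame, genes: Sequence[str], name: str) -> pd.Series:
    sub = _signature_submatrix(matrix, genes)
    logged = np.log2(sub.astype(float) + 1.0)
    centered = logged.sub(logged.median(axis=1), axis=0)
    return pd.Series(centered.mean(axis=0), index=matrix.columns, name=name)


def tds_score(matrix: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Thyroid Differentiation Score: mean median-centered log2(FPM+1)."""
    return _median_centered_log_mean(matrix, signature.genes, "TDS")


def erk_score(matrix: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """ERK/MAPK-output score: same computation as TDS on the ERK gene list."""
    return _median_centered_log_mean(matrix, signature.genes, "ERK")


def nonsynonymous_counts(
    records: Iterable[VariantRecord], samples: Iterable[str]
) -> dict[str, int]:
    """Per-sample count of retained non-synonymous variants (silent excluded)."""
    counts = {s: 0 for s in samples}
    for r in records:
        if r.status in ("pass", "rescued") and r.variant_class != "silent":
            if r.sample_id in counts:
                counts[r.sample_id] += 1
    return counts


def tmb(variant_counts: Mapping[str, int], capture_size_mb: float = 50) -> dict[str, float]:
    """Tumor mutation burden: non-synonymous mutations per captured megabase."""
    if capture_size_mb <= 0:
        raise ConfigError(f"capture size must be positive, got {capture_size_mb}")
    return {s: c / capture_size_mb for s, c in variant_counts.items()}


def score_panel(
    fpm_matrix: pd.DataFrame,
    centroids: ReferenceCentroids,
    tds_signature: GeneSignature,
    erk_signature: GeneSignature,
    variant_counts: Mapping[str, int],
    capture_size_mb: float = 50,
) -> pd.DataFrame:
    """Assemble the per-sample panel: BRS, TDS, ERK, TMB."""
    brs = brs_score(fpm_matrix, centroids)
    tds = tds_score(fpm_matrix, tds_signature)
    erk = erk_score(fpm_matrix, erk_signature)
    burden = tmb(variant_counts, capture_size_mb)
    panel = pd.DataFrame({"BRS": brs, "TDS": tds, "ERK": erk})
    panel["TMB"] = pd.Series(burden).reindex(panel.index).fillna(0.0)
    panel.index.name = "sample_id"
    return panel
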