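"""Expression-matrix construction: gene filtering, FPM normalization, log transform.

Raw gene-level counts are reduced to an analysis-ready matrix in four steps:

1. prevalence filter — keep genes with count > 10 in at least 90% of samples;
2. pseudogene exclusion — drop genes whose biotype contains "pseudogene"
   (mismapping between a gene and its pseudogenes inflates RNA-seq counts);
3. COSMIC rescue — re-add all catalogued oncogenes and tumor suppressor
   genes so cancer-relevant genes are represented regardless of prevalence;
4. normalization — fragments per million (FPM) with median-of-ratios size
   factors (the robust library-size estimate), then log2(FPM + 1).

The matrices are plain pandas DataFrames with genes as rows and samples as
columns; gene metadata (biotype, COSMIC role) travels in a parallel frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import NormalizationError, ValidationError


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) with per-gene metadata.

    ``gene_meta`` is indexed by gene and carries at least ``biotype`` and
    ``cosmic_role`` columns.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("count matrix contains negative entries")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValidationError("gene or sample identifiers are not unique")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """Normalized expression (genes x samples) with provenance.

    ``values`` holds FPM or log2(FPM+1) depending on ``logged``;
    ``provenance`` maps retained genes to their retention reason
    ("prevalence" or "cosmic_rescue").
    """

    values: pd.DataFrame
    size_factors: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)
    logged: bool = False


def filter_genes(counts: CountMatrix, min_count: int = 10, min_fraction: float = 0.9) -> list[str]:
    """Genes with count strictly above ``min_count`` in >= ``min_fraction`` of samples.

    The sample threshold is ceil(min_fraction * n_samples), so 27 of 30
    samples meets a 90% requirement exactly.
    """
    if counts.counts.empty:
        raise ValidationError("cannot filter an empty count matrix")
    n = counts.counts.shape[1]
    need = int(np.ceil(min_fraction * n))
    ok = (counts.counts > min_count).sum(axis=1) >= need
    return list(counts.genes[ok])


def exclude_pseudogenes(genes: list[str], gene_meta: pd.DataFrame) -> list[str]:
    """Drop genes whose biotype contains 'pseudogene' (case-insensitive)."""
    missing = [g for g in genes if g not in gene_meta.index or pd.isna(gene_meta.loc[g, "biotype"])]
    if missing:
        raise ValidationError(f"genes without biotype annotation: {missing[:5]}...")
    return [g for g in genes if "pseudogene" not in str(gene_meta.loc[g, "biotype"]).lower()]


def rescue_cancer_genes(
    retained: list[str], all_genes: list[str], gene_meta: pd.DataFrame
) -> tuple[list[str], dict[str, str]]:
    """Union the retained set with all COSMIC oncogenes/TSGs.

    Rescue overrides both the prevalence filter and the pseudogene exclusion.
    Returns the final gene list (input order preserved) and a provenance map:
    genes already retained keep reason "prevalence"; re-added genes get
    "cosmic_rescue".
    """
    retained_set = set(retained)
    cosmic = {
        g for g in all_genes
        if g in gene_meta.index and str(gene_meta.loc[g, "cosmic_role"]) not in ("none", "nan", "")
    }
    final = [g for g in all_genes if g in retained_set or g in cosmic]
    provenance = {g: ("prevalence" if g in retained_set else "cosmic_rescue") for g in final}
    return final, provenance


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j: factor_j = median over genes of count_gj divided by the
    gene's geometric mean across samples, using only genes with positive
    counts in every sample. Identical columns give factors of exactly 1.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; supply a pseudo-reference "
            "or filter samples before normalization"
        )
    sub = arr[positive]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fpm_normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Fragments per million with a robust (size-factor) library size.

    FPM_gj = count_gj / (factor_j * Lbar) * 1e6 where Lbar is the mean over
    samples of library_size_j / factor_j. With all factors equal to 1 and
    equal library sizes this reduces to counts-per-million.
    """
    if (factors <= 0).any():
        raise NormalizationError("size factors must be positive")
    lib = counts.sum(axis=0)
    lbar = float((lib / factors).mean())
    if lbar <= 0:
        raise NormalizationError("zero total counts")
    return counts / (factors * lbar) * 1e6


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), elementwise; input must be non-negative."""
    if (values.to_numpy() < 0).any():
        raise ValidationError("log transform requires non-negative values")
    return np.log2(values + 1.0)


def build_expression_matrix(
    counts: CountMatrix,
    min_count: int = 10,
    min_fraction: float = 0.9,
    log: bool = True,
) -> ExpressionMatrix:
    """Run the full gene-filter + normalization pipeline on raw counts.

    Size factors are estimated on the full matrix (all genes) before gene
    filtering, as library composition is a sample-level property; the
    prevalence threshold itself is applied to raw counts.
    """
    kept = filter_genes(counts, min_count=min_count, min_fraction=min_fraction)
    kept = exclude_pseudogenes(kept, counts.gene_meta)
    final, provenance = rescue_cancer_genes(kept, list(counts.genes), counts.gene_meta)
    factors = size_factors_median_of_ratios(counts.counts)
    fpm = fpm_normalize(counts.counts.loc[final], factors)
    values = log_transform(fpm) if log else fpm
    return ExpressionMatrix(values=values, size_factors=factors, provenance=provenance, logged=log)


# ---------------------------------------------------------------------------
# Readers / writers

META_COLUMNS = ["biotype", "cosmic_role"]


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Read a genes-as-rows TSV with 'biotype' and 'cosmic_role' metadata columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    gene_meta = df[meta_cols].copy()
    counts = df.drop(columns=meta_cols).astype(int)
    return CountMatrix(counts=counts, gene_meta=gene_meta)


def write_counts_tsv(matrix: CountMatrix, path: str | Path, header: str | None = None) -> None:
    out = pd.concat([matrix.gene_meta, matrix.counts], axis=1)
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        out.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_expression_tsv(values: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        values.to_csv(fh, sep="\t", index_label="gene", float_format="%.6g", lineterminator="\n")


def read_counts_mtx(mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path,
                    meta: pd.DataFrame | None = None) -> CountMatrix:
    """Optional sparse MTX reader (MatrixMarket genes x samples + id lists)."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray().astype(int)
    genes = pd.read_csv(genes_path, header=None)[0].astype(str).tolist()
    samples = pd.read_csv(samples_path, header=None)[0].astype(str).tolist()
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    if meta is None:
        meta = pd.DataFrame({"biotype": "protein_coding", "cosmic_role": "none"}, index=genes)
    return CountMatrix(counts=counts, gene_meta=meta)
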