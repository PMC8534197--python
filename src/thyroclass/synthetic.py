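"""Synthetic thyroid-tumor cohorts with known ground truth.

Generates everything the downstream stages consume — a negative-binomial
count matrix with two expression archetypes (BRAF-like and RAS-like),
annotated somatic variant tables, STAR-Fusion-style fusion tables, and a
labelled reference expression matrix for centroid fitting — together with
the ground-truth labels needed to verify each stage.

The default configuration mirrors a 30-sample follicular-patterned tumor
cohort: roughly a third of samples BRAF-like and two thirds RAS-like,
14/30 driver-negative, RAS-like positives split between RAS point mutations
and PAX8-PPARg fusions, and per-archetype fusion rates of 1.0 and 2.8
fusions per sample. Signature genes (71 BRS-like, 16 TDS-like, 52 ERK-like)
receive archetype-dependent log2 shifts: BRS-like genes split symmetrically
between the archetypes so both score signs occur, ERK-like genes are up in
BRAF-like samples (high MAPK output) and TDS-like genes are up in RAS-like
samples (retained thyroid differentiation).

All randomness flows from ``config.seed`` through named sub-streams, so the
gene universe and sample truth are shared by every generator and each table
is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .expression import CountMatrix, ExpressionMatrix, build_expression_matrix
from .fusions import FusionRecord
from .variants import VariantRecord

BRAF_LIKE = "BRAF-like"
RAS_LIKE = "RAS-like"

# named RNG sub-streams (entropy = [seed, code])
_GENES, _SAMPLES, _COUNTS, _VARIANTS, _FUSIONS, _REFERENCE = range(6)

#: COSMIC-style cancer gene pool used for rescue-path variants.
COSMIC_POOL = [
    ("TP53", "TSG"), ("PTEN", "TSG"), ("RB1", "TSG"), ("SPOP", "TSG"),
    ("DICER1", "TSG"), ("EIF1AX", "oncogene"), ("PIK3CA", "oncogene"),
    ("AKT1", "oncogene"), ("CTNNB1", "oncogene"), ("TERT", "oncogene"),
]

#: Fusion transcripts recurrently seen in normal thyroid tissue (blacklist pool).
NORMAL_FUSION_POOL = [
    ("TFG", "GPR128"), ("CTBS", "GNG5"), ("AZGP1", "GJC3"), ("SIDT2", "TAGLN"),
]

_PSEUDO_BIOTYPES = [
    "processed_pseudogene", "unprocessed_pseudogene",
    "transcribed_processed_pseudogene", "polymorphic_pseudogene",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``archetype_effect`` is the total log2 fold-shift between archetypes for
    signature genes (each archetype moves +-effect/2 from the gene's base
    mean). ``dispersion`` is the negative-binomial dispersion alpha in
    var = mu + alpha * mu^2.
    """

    n_samples: int = 30
    n_genes: int = 2000
    n_brs_genes: int = 71
    n_tds_genes: int = 16
    n_erk_genes: int = 52
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {BRAF_LIKE: 1 / 3, RAS_LIKE: 2 / 3}
    )
    fraction_driver_negative: float = 14 / 30
    fraction_pax8_fusion: float = 0.2  # of RAS-like driver-positives
    archetype_effect: float = 2.0
    dispersion: float = 0.2
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    n_background_variants: int = 400
    fraction_normal_shared: float = 0.10
    fraction_common_population: float = 0.15
    fraction_low_quality: float = 0.10
    fraction_cosmic_in_filtered: float = 0.05
    fraction_silent: float = 0.25
    fraction_pseudogene: float = 0.05
    fraction_cosmic_genes: float = 0.03
    fusion_rate_by_archetype: Mapping[str, float] = field(
        default_factory=lambda: {BRAF_LIKE: 1.0, RAS_LIKE: 2.8}
    )
    background_fail_fusion_rate: float = 1.0
    blacklist_fusion_rate: float = 0.5
    n_reference_braf: int = 26
    n_reference_ras: int = 61
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ConfigError("n_samples and n_genes must be positive")
        n_sig = self.n_brs_genes + self.n_tds_genes + self.n_erk_genes
        if n_sig > self.n_genes:
            raise ConfigError("signature genes exceed the gene universe")
        if abs(sum(self.archetype_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("archetype_fractions must sum to 1")
        for name in (
            "fraction_driver_negative", "fraction_pax8_fusion", "fraction_normal_shared",
            "fraction_common_population", "fraction_low_quality",
            "fraction_cosmic_in_filtered", "fraction_silent",
            "fraction_pseudogene", "fraction_cosmic_genes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_background_variants < 0:
            raise ConfigError("n_background_variants must be non-negative")
        if any(r < 0 for r in self.fusion_rate_by_archetype.values()):
            raise ConfigError("fusion rates must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth planted by the generators."""

    archetype: dict[str, str]  # sample -> BRAF-like | RAS-like
    driver_status: dict[str, str]  # sample -> positive-BRAF | positive-RAS | positive-PAX8-PPARg | negative
    planted_variants: list[VariantRecord] = field(default_factory=list)
    planted_fusions: list[FusionRecord] = field(default_factory=list)

    def samples(self) -> list[str]:
        return list(self.archetype)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


@dataclass
class _GeneUniverse:
    genes: list[str]
    base_means: np.ndarray
    direction: np.ndarray  # +1 = up in BRAF-like, -1 = up in RAS-like, 0 = no shift
    meta: pd.DataFrame
    brs_genes: list[str]
    tds_genes: list[str]
    erk_genes: list[str]


def _gene_universe(config: CohortConfig) -> _GeneUniverse:
    """Gene ids, base means, archetype directions and metadata (seed-stable)."""
    rng = _rng(config, _GENES)
    g = config.n_genes
    genes = [f"G{i:05d}" for i in range(g)]
    order = rng.permutation(g)
    n_brs, n_tds, n_erk = config.n_brs_genes, config.n_tds_genes, config.n_erk_genes
    brs_idx = order[:n_brs]
    tds_idx = order[n_brs:n_brs + n_tds]
    erk_idx = order[n_brs + n_tds:n_brs + n_tds + n_erk]
    sig_idx = np.concatenate([brs_idx, tds_idx, erk_idx])

    # log-normal base expression; signature genes drawn well-expressed so they
    # survive the prevalence filter even when shifted down by effect/2
    base = rng.lognormal(mean=np.log(80.0), sigma=1.6, size=g)
    base[sig_idx] = rng.lognormal(mean=np.log(300.0), sigma=0.5, size=sig_idx.size)

    direction = np.zeros(g)
    half = n_brs // 2
    direction[brs_idx[:half]] = 1.0
    direction[brs_idx[half:]] = -1.0
    direction[tds_idx] = -1.0  # thyroid differentiation retained in RAS-like
    direction[erk_idx] = 1.0   # MAPK output high in BRAF-like

    biotype = np.array(["protein_coding"] * g, dtype=object)
    non_sig = np.setdiff1d(np.arange(g), sig_idx)
    n_pseudo = int(round(config.fraction_pseudogene * g))
    pseudo_idx = rng.choice(non_sig, size=min(n_pseudo, non_sig.size), replace=False)
    biotype[pseudo_idx] = rng.choice(_PSEUDO_BIOTYPES, size=pseudo_idx.size)

    cosmic = np.array(["none"] * g, dtype=object)
    n_cosmic = int(round(config.fraction_cosmic_genes * g))
    cosmic_idx = rng.choice(non_sig, size=min(n_cosmic, non_sig.size), replace=False)
    cosmic[cosmic_idx] = rng.choice(["oncogene", "TSG"], size=cosmic_idx.size)

    meta = pd.DataFrame({"biotype": biotype, "cosmic_role": cosmic}, index=genes)
    return _GeneUniverse(
        genes=genes,
        base_means=base,
        direction=direction,
        meta=meta,
        brs_genes=[genes[i] for i in brs_idx],
        tds_genes=[genes[i] for i in tds_idx],
        erk_genes=[genes[i] for i in erk_idx],
    )


def signature_genes(config: CohortConfig) -> dict[str, list[str]]:
    """The planted signature gene lists {BRS, TDS, ERK} for this config."""
    u = _gene_universe(config)
    return {"BRS": u.brs_genes, "TDS": u.tds_genes, "ERK": u.erk_genes}


def _sample_truth(config: CohortConfig) -> CohortTruth:
    """Archetype, driver status and planted driver lesions per sample."""
    rng = _rng(config, _SAMPLES)
    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    n_braf = int(round(config.archetype_fractions.get(BRAF_LIKE, 0.0) * n))
    arche = np.array([BRAF_LIKE] * n_braf + [RAS_LIKE] * (n - n_braf), dtype=object)
    rng.shuffle(arche)
    archetype = dict(zip(samples, arche))

    driver: dict[str, str] = {}
    planted_v: list[VariantRecord] = []
    planted_f: list[FusionRecord] = []
    for label in (BRAF_LIKE, RAS_LIKE):
        group = [s for s in samples if archetype[s] == label]
        n_neg = int(round(config.fraction_driver_negative * len(group)))
        neg = set(rng.choice(group, size=n_neg, replace=False)) if n_neg else set()
        for s in group:
            if s in neg:
                driver[s] = "negative"
            elif label == BRAF_LIKE:
                driver[s] = "positive-BRAF"
                planted_v.append(VariantRecord(
                    sample_id=s, chrom="7", pos=140453136, ref="A", alt="T",
                    gene="BRAF", variant_class="missense",
                    qc=float(rng.uniform(40, 90)), cosmic_role="oncogene",
                ))
            else:
                if rng.random() < config.fraction_pax8_fusion:
                    driver[s] = "positive-PAX8-PPARg"
                    planted_f.append(FusionRecord(
                        sample_id=s, gene5="PAX8", gene3="PPARG",
                        junction_reads=int(rng.integers(20, 80)),
                        spanning_frags=int(rng.integers(20, 80)),
                        ffpm=float(rng.uniform(0.5, 3.0)),
                    ))
                else:
                    driver[s] = "positive-RAS"
                    planted_v.append(VariantRecord(
                        sample_id=s, chrom="1", pos=115256529, ref="T", alt="C",
                        gene="NRAS", variant_class="missense",
                        qc=float(rng.uniform(40, 90)), cosmic_role="oncogene",
                    ))
    return CohortTruth(
        archetype=archetype, driver_status=driver,
        planted_variants=planted_v, planted_fusions=planted_f,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (Poisson if 0)."""
    if dispersion <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def _simulate_counts(
    config: CohortConfig,
    universe: _GeneUniverse,
    archetypes: np.ndarray,
    samples: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    lo, hi = config.library_size_range
    lib = rng.integers(lo, hi + 1, size=len(samples)).astype(float)
    arch_sign = np.where(archetypes == BRAF_LIKE, 1.0, -1.0)
    # genes x samples mean: base * 2^(dir * sign * effect/2), scaled to library size
    shift = np.outer(universe.direction, arch_sign) * (config.archetype_effect / 2.0)
    mu = universe.base_means[:, None] * np.power(2.0, shift)
    mu = mu * (lib / lib.mean())[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)
    return pd.DataFrame(counts, index=universe.genes, columns=samples)


def generate_counts(config: CohortConfig) -> tuple[CountMatrix, CohortTruth]:
    """Simulate the cohort count matrix and its ground truth."""
    universe = _gene_universe(config)
    truth = _sample_truth(config)
    samples = truth.samples()
    arche = np.array([truth.archetype[s] for s in samples], dtype=object)
    counts = _simulate_counts(config, universe, arche, samples, _rng(config, _COUNTS))
    return CountMatrix(counts=counts, gene_meta=universe.meta.copy()), truth


def generate_variant_table(config: CohortConfig, truth: CohortTruth) -> list[VariantRecord]:
    """Planted driver variants plus stratified background calls.

    Background strata per sample: clean calls, low-mapping-quality calls
    (QC < 20), population-common calls (AF > 0.001 in gnomAD or ABraOM),
    and calls shared with the normal pool; a configurable fraction of the
    filtered strata falls in COSMIC genes so the rescue path is exercised.
    """
    rng = _rng(config, _VARIANTS)
    records = [v.copy() for v in truth.planted_variants]
    classes = ["missense", "nonsense", "frameshift_indel", "inframe_indel", "splice", "other"]
    class_p = [0.62, 0.08, 0.10, 0.06, 0.08, 0.06]

    # shared pool of normal-tissue positions, reused across samples
    n_normal_pool = max(1, int(config.fraction_normal_shared * config.n_background_variants * 2))
    normal_pool = [
        (str(rng.integers(1, 23)), int(rng.integers(1_000_000, 200_000_000)))
        for _ in range(n_normal_pool)
    ]

    for sample in truth.samples():
        n_bg = int(rng.poisson(config.n_background_variants))
        strata = rng.choice(
            ["clean", "low_quality", "common", "normal"],
            size=n_bg,
            p=[
                1 - config.fraction_low_quality - config.fraction_common_population
                - config.fraction_normal_shared,
                config.fraction_low_quality,
                config.fraction_common_population,
                config.fraction_normal_shared,
            ],
        )
        for stratum in strata:
            silent = rng.random() < config.fraction_silent
            vclass = "silent" if silent else str(rng.choice(classes, p=class_p))
            in_cosmic = stratum != "clean" and rng.random() < config.fraction_cosmic_in_filtered
            if in_cosmic:
                gene, role = COSMIC_POOL[int(rng.integers(len(COSMIC_POOL)))]
            else:
                gene, role = f"BG{int(rng.integers(1, 5000)):04d}", "none"
            if stratum == "normal":
                chrom, pos = normal_pool[int(rng.integers(len(normal_pool)))]
            else:
                chrom, pos = str(rng.integers(1, 23)), int(rng.integers(1_000_000, 200_000_000))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            qc = float(rng.uniform(0, 19.99)) if stratum == "low_quality" else float(rng.uniform(25, 90))
            af_g = af_a = None
            if stratum == "common":
                if rng.random() < 0.5:
                    af_g = float(rng.uniform(0.0015, 0.05))
                else:
                    af_a = float(rng.uniform(0.0015, 0.05))
            elif rng.random() < 0.3:
                af_g = float(rng.uniform(0, 0.0008))
            records.append(VariantRecord(
                sample_id=sample, chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
                gene=gene, variant_class=vclass, qc=qc,
                af_gnomad=af_g, af_abraom=af_a, cosmic_role=role,
                normal_shared=(stratum == "normal"),
            ))
    return records


def normal_variant_keys(records: list[VariantRecord]) -> set[tuple[str, int, str, str]]:
    """Keys of the normal-shared stratum, for building a NormalVariantSet."""
    return {r.key() for r in records if r.normal_shared}


def generate_fusion_table(config: CohortConfig, truth: CohortTruth) -> list[FusionRecord]:
    """Planted driver fusions plus Poisson background fusions per sample.

    True fusion counts per sample are Poisson with the archetype's configured
    rate and carry passing support; additional below-threshold calls and
    normal-blacklist artifacts are emitted so every filter branch occurs.
    """
    rng = _rng(config, _FUSIONS)
    records = [f.copy() for f in truth.planted_fusions]
    for sample in truth.samples():
        rate = config.fusion_rate_by_archetype.get(truth.archetype[sample], 0.0)
        for _ in range(int(rng.poisson(rate))):
            records.append(FusionRecord(
                sample_id=sample,
                gene5=f"FG{int(rng.integers(1, 500)):03d}",
                gene3=f"FG{int(rng.integers(500, 1000)):03d}",
                junction_reads=10 + int(rng.geometric(0.05)),
                spanning_frags=10 + int(rng.geometric(0.05)),
                ffpm=float(0.1 + rng.exponential(0.8)),
            ))
        for _ in range(int(rng.poisson(config.background_fail_fusion_rate))):
            # weak call: low FFPM, or one/both supports at or below threshold
            mode = rng.random()
            records.append(FusionRecord(
                sample_id=sample,
                gene5=f"FG{int(rng.integers(1, 500)):03d}",
                gene3=f"FG{int(rng.integers(500, 1000)):03d}",
                junction_reads=int(rng.integers(0, 11)) if mode < 0.7 else 10 + int(rng.geometric(0.05)),
                spanning_frags=int(rng.integers(0, 11)),
                ffpm=float(rng.uniform(0, 0.1)) if mode >= 0.4 else float(0.1 + rng.exponential(0.8)),
            ))
        for _ in range(int(rng.poisson(config.blacklist_fusion_rate))):
            g5, g3 = NORMAL_FUSION_POOL[int(rng.integers(len(NORMAL_FUSION_POOL)))]
            records.append(FusionRecord(
                sample_id=sample, gene5=g5, gene3=g3,
                junction_reads=10 + int(rng.geometric(0.05)),
                spanning_frags=10 + int(rng.geometric(0.05)),
                ffpm=float(0.1 + rng.exponential(0.8)),
            ))
    return records


def normal_fusion_blacklist() -> set[tuple[str, str]]:
    """The normal-thyroid fusion transcript blacklist matching the generator."""
    return set(NORMAL_FUSION_POOL)


def generate_reference_matrix(config: CohortConfig) -> tuple[ExpressionMatrix, pd.Series]:
    """Labelled reference cohort (default 26 BRAF V600E + 61 RAS) on FPM scale.

    Shares the gene universe and archetype structure of the synthetic cohort,
    so centroids fitted on it apply to cohorts generated from the same config.
    """
    universe = _gene_universe(config)
    rng = _rng(config, _REFERENCE)
    n_b, n_r = config.n_reference_braf, config.n_reference_ras
    samples = [f"REF_BRAF_{i:03d}" for i in range(1, n_b + 1)] + [
        f"REF_RAS_{i:03d}" for i in range(1, n_r + 1)
    ]
    arche = np.array([BRAF_LIKE] * n_b + [RAS_LIKE] * n_r, dtype=object)
    counts = _simulate_counts(config, universe, arche, samples, rng)
    cm = CountMatrix(counts=counts, gene_meta=universe.meta.copy())
    expr = build_expression_matrix(cm, log=False)
    labels = pd.Series(
        ["BRAF V600E"] * n_b + ["RAS"] * n_r, index=samples, name="label"
    )
    return expr, labels


def write_truth_tsv(truth: CohortTruth, path) -> None:
    df = pd.DataFrame({
        "sample_id": truth.samples(),
        "archetype": [truth.archetype[s] for s in truth.samples()],
        "driver_status": [truth.driver_status[s] for s in truth.samples()],
    })
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
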