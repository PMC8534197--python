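"""Somatic SNV/InDel filter chain for RNA-seq variant calls.

Variants annotated from tumor RNA-seq carry many artifacts and germline
polymorphisms. The chain applied here flags calls with poor mapping quality
(QC < 20), calls common in population databases (allele frequency > 0.001 in
gnomAD or ABraOM), and calls also seen in normal thyroid tissue; flagged calls
in COSMIC-catalogued oncogenes or tumor suppressor genes are then reimported
("rescued") so that known cancer genes are never silently lost. Every record
keeps full provenance: its final status (pass / removed / rescued) and the set
of reasons that flagged it.

Filtering never drops records — each operation only adds removal reasons, so
the three flagging steps commute and the chain is idempotent on its retained
output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ValidationError

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice", "silent", "other"}
)
COSMIC_ROLES = frozenset({"oncogene", "TSG", "none"})

#: MAF-style TSV column order used by readers and writers.
MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "QC",
    "AF_gnomAD",
    "AF_ABraOM",
    "cosmic_role",
    "normal_shared",
]


@dataclass
class VariantRecord:
    """One annotated somatic SNV/InDel call with filter provenance.

    Coordinates are 1-based, VCF-style; indels are assumed left-aligned by the
    upstream caller. ``af_gnomad`` / ``af_abraom`` are population allele
    frequencies in [0, 1], or None when the variant is absent from the
    database (treated as rare).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str = "missense"
    qc: float | None = None
    af_gnomad: float | None = None
    af_abraom: float | None = None
    cosmic_role: str = "none"
    normal_shared: bool = False  # input annotation: also seen in normal tissue
    status: str = "pass"
    removal_reasons: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos} ({self.key()})")
        for name, af in (("af_gnomad", self.af_gnomad), ("af_abraom", self.af_abraom)):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValidationError(f"{name}={af} outside [0, 1] for {self.key()}")
        if self.cosmic_role not in COSMIC_ROLES:
            raise ValidationError(f"unknown cosmic_role {self.cosmic_role!r}")
        self.removal_reasons = set(self.removal_reasons)

    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) — the identity used for normal subtraction."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def copy(self) -> "VariantRecord":
        return replace(self, removal_reasons=set(self.removal_reasons))


class NormalVariantSet:
    """Set of (chrom, pos, ref, alt) keys observed in normal tissue.

    Used to subtract calls shared with normal thyroid data (e.g. ENCODE
    normals processed under the same pipeline).
    """

    def __init__(self, keys: Iterable[tuple[str, int, str, str]] = ()):
        self.keys = set(keys)

    def __contains__(self, key) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalVariantSet":
        df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
        keys = {
            (str(r.Chromosome), int(r.Start_Position), str(r.Reference_Allele), str(r.Tumor_Seq_Allele2))
            for r in df.itertuples()
        }
        return cls(keys)

    @classmethod
    def from_records(cls, records: Iterable["VariantRecord"]) -> "NormalVariantSet":
        """Build the set from records annotated as normal_shared (e.g. a read-back MAF)."""
        return cls(r.key() for r in records if r.normal_shared)


def _copy_all(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    return [r.copy() for r in records]


def filter_by_quality(records: Sequence[VariantRecord], min_qc: float = 20) -> list[VariantRecord]:
    """Flag records with mapping quality strictly below ``min_qc``.

    The boundary is strict: QC exactly at the threshold passes. Records are
    returned as copies with ``low_quality`` added to their removal reasons;
    nothing is dropped.
    """
    out = _copy_all(records)
    for r in out:
        if r.qc is None:
            raise ValidationError(f"record {r.sample_id}:{r.key()} has no QC value")
        if r.qc < min_qc:
            r.removal_reasons.add("low_quality")
    return out


def filter_by_population_frequency(
    records: Sequence[VariantRecord], max_af: float = 0.001
) -> list[VariantRecord]:
    """Flag records common in either population database (AF strictly > ``max_af``).

    OR semantics across gnomAD and ABraOM; a missing frequency means the
    variant is absent from that database and is treated as rare.
    """
    out = _copy_all(records)
    for r in out:
        gnomad_common = r.af_gnomad is not None and r.af_gnomad > max_af
        abraom_common = r.af_abraom is not None and r.af_abraom > max_af
        if gnomad_common or abraom_common:
            r.removal_reasons.add("common_population")
    return out


def subtract_normal_variants(
    records: Sequence[VariantRecord], normal: NormalVariantSet
) -> list[VariantRecord]:
    """Flag records whose (chrom, pos, ref, alt) key occurs in normal tissue."""
    out = _copy_all(records)
    for r in out:
        if r.key() in normal:
            r.removal_reasons.add("normal_shared")
    return out


def rescue_cosmic_variants(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Resolve final statuses, reimporting flagged variants in COSMIC genes.

    All flagged variants whose gene is a COSMIC oncogene or TSG become
    ``rescued`` (their reasons are retained for provenance); other flagged
    records become ``removed``; unflagged records are ``pass``. Rescue applies
    to every removal reason, including low mapping quality — such records are
    worth a second look, and the audit writer marks them.
    """
    out = _copy_all(records)
    for r in out:
        if not r.removal_reasons:
            r.status = "pass"
        elif r.cosmic_role in ("oncogene", "TSG"):
            r.status = "rescued"
        else:
            r.status = "removed"
    return out


def run_variant_filter_chain(
    records: Sequence[VariantRecord],
    normal: NormalVariantSet | None = None,
    min_qc: float = 20,
    max_af: float = 0.001,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Run quality -> population -> normal-subtraction -> COSMIC rescue.

    Returns the retained records (status pass or rescued) and an audit table
    listing every input record with its final status and reasons. The three
    flagging steps only add reasons, so their order does not affect the
    outcome.
    """
    normal = normal or NormalVariantSet()
    staged = filter_by_quality(records, min_qc=min_qc)
    staged = filter_by_population_frequency(staged, max_af=max_af)
    staged = subtract_normal_variants(staged, normal)
    staged = rescue_cosmic_variants(staged)
    retained = [r for r in staged if r.status in ("pass", "rescued")]
    audit = audit_table(staged)
    return retained, audit


def audit_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-record audit with status, reasons and a low-quality-rescue warning."""
    rows = []
    for r in records:
        rows.append(
            {
                "Tumor_Sample_Barcode": r.sample_id,
                "Hugo_Symbol": r.gene,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Variant_Classification": r.variant_class,
                "status": r.status,
                "removal_reasons": ";".join(sorted(r.removal_reasons)),
                "warning": (
                    "rescued_low_quality"
                    if r.status == "rescued" and "low_quality" in r.removal_reasons
                    else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
            "status",
            "removal_reasons",
            "warning",
        ],
    )


# ---------------------------------------------------------------------------
# Readers / writers


def _opt_float(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a MAF-style TSV into VariantRecords (columns per ``MAF_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    missing = [c for c in MAF_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValidationError(f"MAF file {path} missing columns: {missing}")
    records = []
    for row in df.itertuples():
        records.append(
            VariantRecord(
                sample_id=str(row.Tumor_Sample_Barcode),
                chrom=str(row.Chromosome),
                pos=int(row.Start_Position),
                ref=str(row.Reference_Allele),
                alt=str(row.Tumor_Seq_Allele2),
                gene=str(row.Hugo_Symbol),
                variant_class=str(row.Variant_Classification),
                qc=_opt_float(getattr(row, "QC", None)),
                af_gnomad=_opt_float(getattr(row, "AF_gnomAD", None)),
                af_abraom=_opt_float(getattr(row, "AF_ABraOM", None)),
                cosmic_role=str(getattr(row, "cosmic_role", "none") or "none"),
                normal_shared=bool(int(getattr(row, "normal_shared", 0) or 0)),
            )
        )
    return records


def write_maf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a MAF-style TSV (LF endings, fixed column order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MAF_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.gene,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.variant_class,
                    "" if r.qc is None else f"{r.qc:.6g}",
                    "" if r.af_gnomad is None else f"{r.af_gnomad:.6g}",
                    "" if r.af_abraom is None else f"{r.af_abraom:.6g}",
                    r.cosmic_role,
                    int(r.normal_shared),
                ]
            )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a minimal annotated VCF.

    QC is taken from QUAL; gene, variant class, population frequencies and
    COSMIC role come from the INFO keys GENE, VC, AF_GNOMAD, AF_ABRAOM and
    COSMIC_ROLE. The sample id is the single genotype column name, or the
    file stem for site-only VCFs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else Path(path).stem
    records = []
    for v in vcf:
        info = dict(v.INFO)
        records.append(
            VariantRecord(
                sample_id=sample,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                gene=str(info.get("GENE", "")),
                variant_class=str(info.get("VC", "other")),
                qc=None if v.QUAL is None else float(v.QUAL),
                af_gnomad=_opt_float(info.get("AF_GNOMAD")),
                af_abraom=_opt_float(info.get("AF_ABRAOM")),
                cosmic_role=str(info.get("COSMIC_ROLE", "none")),
            )
        )
    return records
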