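"""Gene-fusion call filtering and per-group fusion burden.

Fusion calls from RNA-seq (STAR-Fusion-style tables) are filtered on
expression support — fusion fragments per million total reads (FFPM)
strictly above 0.1 and junction-read and spanning-fragment counts strictly
above 10 — and against a blacklist of fusion transcripts also detected in
normal thyroid tissue. As in the variant chain, filters only annotate
records; nothing is dropped, and the record count is conserved.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, ValidationError

FUSION_COLUMNS = [
    "#FusionName",
    "LeftGene",
    "RightGene",
    "JunctionReadCount",
    "SpanningFragCount",
    "FFPM",
    "Sample",
]


@dataclass
class FusionRecord:
    """One fusion call: 5' and 3' partner genes with support statistics."""

    sample_id: str
    gene5: str
    gene3: str
    junction_reads: int
    spanning_frags: int
    ffpm: float
    status: str = "pass"
    removal_reasons: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.junction_reads < 0 or self.spanning_frags < 0 or self.ffpm < 0:
            raise ValidationError(
                f"negative support for {self.name()} in {self.sample_id}"
            )
        self.removal_reasons = set(self.removal_reasons)

    def name(self) -> str:
        return f"{self.gene5}--{self.gene3}"

    def pair(self) -> tuple[str, str]:
        """Ordered (5', 3') gene pair; orientation matters for fusions."""
        return (self.gene5, self.gene3)

    def copy(self) -> "FusionRecord":
        return replace(self, removal_reasons=set(self.removal_reasons))


def _resolve(records: list[FusionRecord]) -> list[FusionRecord]:
    for r in records:
        r.status = "pass" if not r.removal_reasons else "removed"
    return records


def filter_fusions(
    records: Sequence[FusionRecord],
    min_ffpm: float = 0.1,
    min_support: int = 10,
    support_mode: str = "each",
) -> list[FusionRecord]:
    """Flag fusions with weak expression support.

    FFPM must be strictly greater than ``min_ffpm``. With ``support_mode``
    "each" (default) both the junction-read and the spanning-fragment counts
    must strictly exceed ``min_support``; with "sum" their total must.
    """
    if support_mode not in ("each", "sum"):
        raise ConfigError(f"unknown support_mode {support_mode!r}; use 'each' or 'sum'")
    out = [r.copy() for r in records]
    for r in out:
        if r.ffpm <= min_ffpm:
            r.removal_reasons.add("low_ffpm")
        if support_mode == "each":
            supported = r.junction_reads > min_support and r.spanning_frags > min_support
        else:
            supported = r.junction_reads + r.spanning_frags > min_support
        if not supported:
            r.removal_reasons.add("low_support")
    return _resolve(out)


def subtract_normal_fusions(
    records: Sequence[FusionRecord], blacklist: Iterable[tuple[str, str]]
) -> list[FusionRecord]:
    """Flag fusion transcripts also detected in normal tissue.

    Matching is by ordered (5', 3') gene pair — the reversed pair is a
    different transcript and is not flagged.
    """
    blacklist = set(blacklist)
    out = [r.copy() for r in records]
    for r in out:
        if r.pair() in blacklist:
            r.removal_reasons.add("normal_artifact")
    return _resolve(out)


def fusion_burden(
    records: Sequence[FusionRecord], groups: Mapping[str, str]
) -> dict[str, float]:
    """Mean number of passing fusions per sample, per group.

    Every sample in ``groups`` counts toward its group's denominator even
    with zero passing fusions; a group with no fusions has burden 0.0. A
    record whose sample is missing from ``groups`` is an error.
    """
    counts = {sample: 0 for sample in groups}
    for r in records:
        if r.sample_id not in groups:
            raise ValidationError(f"sample {r.sample_id!r} not mapped to a group")
        if r.status == "pass":
            counts[r.sample_id] += 1
    burden: dict[str, list[int]] = {}
    for sample, group in groups.items():
        burden.setdefault(group, []).append(counts[sample])
    return {g: sum(v) / len(v) for g, v in sorted(burden.items())}


def passing_counts(records: Sequence[FusionRecord], samples: Iterable[str]) -> dict[str, int]:
    """Per-sample count of passing fusions (zero-filled over ``samples``)."""
    counts = {s: 0 for s in samples}
    for r in records:
        if r.status == "pass" and r.sample_id in counts:
            counts[r.sample_id] += 1
    return counts


def read_fusion_tsv(path: str | Path) -> list[FusionRecord]:
    """Read a STAR-Fusion-style TSV ('GENE5--GENE3' in #FusionName)."""
    df = pd.read_csv(path, sep="\t")
    if "#FusionName" not in df.columns:
        raise ValidationError(f"{path} is not a fusion table (no #FusionName column)")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        name = str(d["_0"]) if "_0" in d else str(d["#FusionName"])
        if "LeftGene" in df.columns:
            g5, g3 = str(d["LeftGene"]), str(d["RightGene"])
        else:
            g5, g3 = name.split("--", 1)
        records.append(
            FusionRecord(
                sample_id=str(d.get("Sample", Path(path).stem)),
                gene5=g5,
                gene3=g3,
                junction_reads=int(d["JunctionReadCount"]),
                spanning_frags=int(d["SpanningFragCount"]),
                ffpm=float(d["FFPM"]),
            )
        )
    return records


def write_fusion_tsv(
    records: Sequence[FusionRecord], path: str | Path, with_status: bool = False
) -> None:
    cols = list(FUSION_COLUMNS) + (["status", "removal_reasons"] if with_status else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = [
                r.name(),
                r.gene5,
                r.gene3,
                r.junction_reads,
                r.spanning_frags,
                f"{r.ffpm:.6g}",
                r.sample_id,
            ]
            if with_status:
                row += [r.status, ";".join(sorted(r.removal_reasons))]
            writer.writerow(row)
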