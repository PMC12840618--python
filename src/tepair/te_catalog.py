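"""Transposable-element annotation catalog and flank queries.

TE annotations arrive as a BED-like TSV (chrom, start, end, family, strand;
0-based half-open intervals), emulating DFAM/RepeatMasker-style tables. For
fast retrieval of the elements flanking a contact anchor, records are
bucketed into 10 kb bins; a flank query returns every element whose CENTER
lies within ±11 kb of the queried position. Membership by element center —
rather than any-overlap — is the same rule the sliding-window pairing
analysis uses, so the two stages agree on which element "belongs" to a
locus.

Family identity is the verbatim annotation name (MIRb is not MIR3). An
optional family map collapses names into superfamilies (ALU, L1, L2, MIR,
ERVL, SVA, ...) for coarser summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TERecord",
    "TEIndex",
    "read_te_bed",
    "write_te_bed",
    "build_index",
    "query_flank",
    "apply_family_map",
    "default_superfamily",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TERecord:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    family: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TE interval empty: {self.start} >= {self.end}")
        if not self.family:
            raise ValueError("TE family name empty")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TEIndex:
    """TE records bucketed by the 10 kb bins their intervals overlap."""

    bucket_size: int = 10_000
    buckets: dict[tuple[str, int], list[TERecord]] = field(default_factory=dict)
    n_records: int = 0


def read_te_bed(path: str | Path) -> list[TERecord]:
    """Parse a BED-like TSV (>=5 columns); '#' lines skipped, malformed or
    inverted-interval lines counted, skipped and logged."""
    records: list[TERecord] = []
    n_bad = 0
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if len(fields) < 5:
                raise ValueError("need >= 5 columns")
            rec = TERecord(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                family=fields[3],
                strand=fields[4],
            )
        except ValueError:
            n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        log.warning("%s: skipped %d malformed TE line(s)", path, n_bad)
    if not records:
        log.warning("%s: no TE records parsed", path)
    return records


def write_te_bed(records: list[TERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tfamily\tstrand\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t{r.strand}\n")


def build_index(records: list[TERecord], bucket_size: int = 10_000) -> TEIndex:
    """Register each record in every bucket overlapped by [start, end)."""
    index = TEIndex(bucket_size=bucket_size)
    for rec in records:
        first = rec.start // bucket_size
        last = (rec.end - 1) // bucket_size
        for b in range(first, last + 1):
            index.buckets.setdefault((rec.chrom, b), []).append(rec)
        index.n_records += 1
    return index


def query_flank(
    index: TEIndex, chrom: str, pos: int, flank: int = 11_000
) -> list[TERecord]:
    """Elements whose center lies in ``[pos - flank, pos + flank]``
    (inclusive bounds), deduplicated and sorted by center."""
    lo, hi = pos - flank, pos + flank
    first = max(lo, 0) // index.bucket_size
    last = max(hi, 0) // index.bucket_size
    seen: set[TERecord] = set()
    out: list[TERecord] = []
    found_chrom = False
    for b in range(first, last + 1):
        bucket = index.buckets.get((chrom, b))
        if bucket is None:
            continue
        found_chrom = True
        for rec in bucket:
            if lo <= rec.center <= hi and rec not in seen:
                seen.add(rec)
                out.append(rec)
    if not found_chrom and not any(c == chrom for c, _ in index.buckets):
        log.warning("query_flank: unknown chromosome %r", chrom)
    out.sort(key=lambda r: (r.center, r.start, r.family))
    return out


# Superfamily aggregation -------------------------------------------------

_SUPERFAMILY_PREFIXES = [
    ("Alu", "ALU"),
    ("FLAM", "ALU"),
    ("FRAM", "ALU"),
    ("L1", "L1"),
    ("HAL1", "L1"),
    ("L2", "L2"),
    ("MIR", "MIR"),
    ("ERVL", "ERVL"),
    ("MLT", "ERVL"),
    ("MST", "ERVL"),
    ("THE1", "ERVL"),
    ("SVA", "SVA"),
]


def default_superfamily(family: str) -> str:
    """Map a repeat family name onto a coarse superfamily by prefix; names
    with no known prefix are returned unchanged."""
    for prefix, superfamily in _SUPERFAMILY_PREFIXES:
        if family.startswith(prefix):
            return superfamily
    return family


def apply_family_map(
    records: list[TERecord], mapping: dict[str, str] | None = None
) -> list[TERecord]:
    """Rename families via an explicit map (or the built-in prefix rules)."""
    if mapping is None:
        rename = default_superfamily
    else:
        rename = lambda fam: mapping.get(fam, fam)  # noqa: E731
    return [
        TERecord(r.chrom, r.start, r.end, rename(r.family), r.strand)
        for r in records
    ]
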