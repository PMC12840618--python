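"""Reading .pairs contact streams and binning them into sparse contact maps.

A contact is one sequenced read pair whose two ends mark genomic loci that
were in 3D proximity. The 4DN ``.pairs`` text format lists one contact per
line: readID, chrom1, pos1, chrom2, pos2, strand1, strand2 (extra trailing
columns tolerated, ``#`` header lines skipped). Analysis is restricted to
intra-chromosomal contacts separated by 8–40 kb — local loops, past the
immediate-neighbour decay — and accumulated on a fixed 600 bp bin lattice.

Large ``.pairs`` files are thinned with a systematic :class:`SamplingPlan`
(skip an initial block of raw data lines, then alternate take/skip cycles);
the plan counts raw data lines, not retained contacts, so the same plan
selects the same physical read pairs regardless of downstream filters.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ContactRecord",
    "SamplingPlan",
    "BinnedContactMap",
    "stream_pairs",
    "filter_band",
    "bin_contacts",
    "load_contact_map",
    "read_chrom_sizes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactRecord:
    """One read pair; same-chromosome records are normalised to pos1 <= pos2."""

    chrom1: str
    pos1: int  # 1-based, as in the .pairs format
    chrom2: str
    pos2: int
    strand1: str = "+"
    strand2: str = "+"

    def normalized(self) -> "ContactRecord":
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            return ContactRecord(
                self.chrom2, self.pos2, self.chrom1, self.pos1,
                self.strand2, self.strand1,
            )
        return self


@dataclass(frozen=True)
class SamplingPlan:
    """Systematic skip/take/skip schedule over raw data-line indices."""

    initial_skip: int = 0
    take: int | None = None  # None = take everything after the initial skip
    cycle_skip: int = 0

    def __post_init__(self) -> None:
        if self.initial_skip < 0 or self.cycle_skip < 0:
            raise ValueError("skips must be >= 0")
        if self.take is not None and self.take <= 0:
            raise ValueError("take must be positive")

    def selects(self, index: int) -> bool:
        """Whether the 0-based raw data-line ``index`` is retained."""
        if index < self.initial_skip:
            return False
        if self.take is None:
            return True
        return (index - self.initial_skip) % (self.take + self.cycle_skip) < self.take

    @classmethod
    def everything(cls) -> "SamplingPlan":
        return cls(0, None, 0)


@dataclass
class BinnedContactMap:
    """Sparse upper-triangular contact counts on a fixed bp lattice.

    Keys are ``(chrom, bin_i, bin_j)`` with ``bin_i <= bin_j`` and 0-based
    bins of ``bin_size`` bp; ``counts[key]`` is the number of retained read
    pairs whose (1-based) positions fall in that bin pair.
    """

    bin_size: int = 600
    counts: dict[tuple[str, int, int], int] = field(default_factory=dict)
    total_records: int = 0
    chrom_sizes: dict[str, int] | None = None

    def n_bins(self, chrom: str) -> int | None:
        if self.chrom_sizes is None or chrom not in self.chrom_sizes:
            return None
        return -(-self.chrom_sizes[chrom] // self.bin_size)  # ceil

    def get(self, chrom: str, bin_i: int, bin_j: int) -> int:
        return self.counts.get((chrom, bin_i, bin_j), 0)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def stream_pairs(
    path: str | Path, plan: SamplingPlan | None = None
) -> Iterator[ContactRecord]:
    """Stream normalised :class:`ContactRecord` from a ``.pairs`` file.

    Header lines (``#``) are ignored; the sampling plan indexes raw data
    lines. Malformed data lines are counted and skipped with one summary
    warning; a nonempty file yielding no parseable data line at all raises.
    """
    plan = plan or SamplingPlan.everything()
    n_data = n_bad = n_parsed = n_selected = 0
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            index = n_data
            n_data += 1
            if not plan.selects(index):
                continue
            n_selected += 1
            fields = line.rstrip("\n").split("\t")
            try:
                rec = ContactRecord(
                    chrom1=fields[1],
                    pos1=int(fields[2]),
                    chrom2=fields[3],
                    pos2=int(fields[4]),
                    strand1=fields[5] if len(fields) > 5 else "+",
                    strand2=fields[6] if len(fields) > 6 else "+",
                )
            except (IndexError, ValueError):
                n_bad += 1
                continue
            if rec.pos1 < 1 or rec.pos2 < 1:
                n_bad += 1
                continue
            n_parsed += 1
            yield rec.normalized()
    if n_bad:
        log.warning("%s: skipped %d malformed data line(s)", path, n_bad)
    if n_selected and n_parsed == 0:
        raise ValueError(f"{path}: no parseable data line in a nonempty file")


def filter_band(
    record: ContactRecord, min_sep: int = 8_000, max_sep: int = 40_000
) -> bool:
    """True iff the contact is intra-chromosomal with separation in
    ``[min_sep, max_sep]`` (both bounds inclusive)."""
    if record.chrom1 != record.chrom2:
        return False
    sep = record.pos2 - record.pos1
    return min_sep <= sep <= max_sep


def bin_contacts(
    records: Iterable[ContactRecord],
    bin_size: int = 600,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedContactMap:
    """Accumulate band-filtered records into a sparse binned map.

    Bin index is ``floor((pos - 1) / bin_size)`` — 0-based bins over the
    1-based coordinate stream. The lattice phase matters downstream: the
    misbinning control relies on re-binning the same records at an
    off-lattice bin size.
    """
    cmap = BinnedContactMap(bin_size=bin_size, chrom_sizes=chrom_sizes)
    for rec in records:
        bi = (rec.pos1 - 1) // bin_size
        bj = (rec.pos2 - 1) // bin_size
        if bi > bj:
            bi, bj = bj, bi
        key = (rec.chrom1, bi, bj)
        cmap.counts[key] = cmap.counts.get(key, 0) + 1
        cmap.total_records += 1
    return cmap


def load_contact_map(
    path: str | Path,
    plan: SamplingPlan | None = None,
    bin_size: int = 600,
    min_sep: int = 8_000,
    max_sep: int = 40_000,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedContactMap:
    """stream -> band filter -> bin, in one pass."""
    records = (
        r for r in stream_pairs(path, plan) if filter_band(r, min_sep, max_sep)
    )
    return bin_contacts(records, bin_size=bin_size, chrom_sizes=chrom_sizes)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        sizes[name] = int(length)
    return sizes
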