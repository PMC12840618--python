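"""Synthetic genomes, TE catalogs and contact .pairs files with known truth.

The generator manufactures the exact study conditions the analysis assumes:
intra-chromosomal read pairs confined to the 8–40 kb separation band, drawn
per 600 bp bin pair as homogeneous Poisson background, plus *planted* focal
enrichments — ``focal_count`` extra reads inside a single chosen bin pair.
TE catalogs place background elements uniformly (lengths 150–6,000 bp,
spanning Alu-like to L1-like sizes; strand fair-coin), and optionally
*couple* a chosen family to a planted hotspot: with probability
``coupling_prob`` an element of that family is centered within ±1 kb of
BOTH anchor midpoints, i.e. inside the central 2 kb analysis window on each
side. A truth table records every plant and coupling for recovery tests.

Under the homogeneous Poisson background with uniform TE placement the
hot/cold pairing ratio is exactly 1 in expectation, which is what makes the
null-calibration and dose–response checks interpretable.

All randomness flows through explicit integer seeds (no global RNG state),
and output files are byte-identical across runs with the same seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .te_catalog import TERecord, write_te_bed

__all__ = [
    "GenomeSpec",
    "PlantSpec",
    "TruthTable",
    "SyntheticDataset",
    "make_genome",
    "random_plants",
    "plant_te_catalog",
    "generate_pairs_file",
    "simulate_dataset",
    "BIN_SIZE",
]

BIN_SIZE = 600  # generator lattice; the analysis default
MIN_SEP, MAX_SEP = 8_000, 40_000
# bin-pair separations whose lattice distance lies inside the band
MIN_SEP_BINS = -(-MIN_SEP // BIN_SIZE)  # 14
MAX_SEP_BINS = MAX_SEP // BIN_SIZE  # 66
TE_LEN_MIN, TE_LEN_MAX = 150, 6_000
COUPLE_HALF_WINDOW = 1_000  # coupled TE centers within ±1 kb of each anchor

# room for one hotspot plus its ±57 kb coldfield corridor and ±11 kb flanks
MIN_CHROM_LENGTH = 200_000


@dataclass(frozen=True)
class GenomeSpec:
    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def n_bins(self, chrom: str) -> int:
        return self.sizes[chrom] // BIN_SIZE  # complete bins only


@dataclass(frozen=True)
class PlantSpec:
    """One planted focal enrichment on the 600 bp lattice."""

    chrom: str
    anchor1_bin: int
    anchor2_bin: int
    focal_count: int
    coupling_prob: float = 0.0
    coupled_family: str = ""

    def __post_init__(self) -> None:
        sep = (self.anchor2_bin - self.anchor1_bin) * BIN_SIZE
        if not MIN_SEP <= sep <= MAX_SEP:
            raise ValueError(
                f"planted anchor separation {sep} bp outside [{MIN_SEP}, {MAX_SEP}]"
            )
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ValueError("coupling_prob must lie in [0, 1]")
        if self.coupling_prob > 0 and not self.coupled_family:
            raise ValueError("coupling requested but no coupled_family given")
        if self.focal_count < 0:
            raise ValueError("focal_count must be >= 0")

    def anchor_mid(self, which: int) -> int:
        b = self.anchor1_bin if which == 1 else self.anchor2_bin
        return b * BIN_SIZE + BIN_SIZE // 2


@dataclass
class TruthTable:
    """What was planted: one row per PlantSpec, plus the seed used."""

    seed: int
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#seed={self.seed}\n")
            self.frame.to_csv(fh, sep="\t", index=False)


@dataclass
class SyntheticDataset:
    genome: GenomeSpec
    pairs_path: Path
    te_bed_path: Path
    chrom_sizes_path: Path
    truth: TruthTable
    te_records: list[TERecord]


def make_genome(n_chrom: int = 1, length: int = 1_000_000) -> GenomeSpec:
    """Toy genome of ``n_chrom`` chromosomes, each ``length`` bp.

    Names are chrS1, chrS2, ... (the S avoids collision with real
    assemblies). A chromosome must be long enough to host one hotspot plus
    its ±57 kb search corridor and ±11 kb flanks.
    """
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    if length < MIN_CHROM_LENGTH:
        raise ValueError(
            f"length {length} < {MIN_CHROM_LENGTH} bp cannot host a hotspot "
            "plus its search corridor"
        )
    names = tuple(f"chrS{i + 1}" for i in range(n_chrom))
    return GenomeSpec(names=names, lengths=(length,) * n_chrom)


def random_plants(
    genome: GenomeSpec,
    n: int,
    focal_count: int,
    coupling_prob: float = 0.0,
    coupled_family: str = "",
    seed: int = 0,
    min_gap_bins: int = 12,
) -> list[PlantSpec]:
    """Lay out ``n`` isolated plants across the genome.

    Anchor-1 bins are spaced at least ``min_gap_bins`` apart with random
    anchor separations inside the distance band; 100 bins at each
    chromosome end stay empty so every plant keeps a full coldfield
    corridor. The 12-bin default keeps distinct plants' 5x5 grids disjoint
    AND keeps any plant's coupled TEs (within ±1 kb of its anchors) out of
    the central 2 kb window of a neighbouring plant's nearest eligible
    coldfield anchor (5 bins = 3 kb away), so planted coupling cannot leak
    into coldfield baselines.
    """
    rng = np.random.default_rng(seed)
    margin = 100
    slots: list[tuple[str, int]] = []
    for chrom in genome.names:
        n_bins = genome.n_bins(chrom)
        lo, hi = margin, n_bins - margin - MAX_SEP_BINS
        if hi <= lo:
            raise ValueError(f"{chrom} too short to place plants")
        slots.extend((chrom, b) for b in range(lo, hi, min_gap_bins))
    if n > len(slots):
        raise ValueError(f"cannot place {n} plants in {len(slots)} slots")
    chosen = sorted(rng.choice(len(slots), size=n, replace=False))
    plants = []
    for idx in chosen:
        chrom, a1 = slots[idx]
        sep = int(rng.integers(MIN_SEP_BINS + 1, MAX_SEP_BINS))  # off band edges
        plants.append(
            PlantSpec(chrom, a1, a1 + sep, focal_count, coupling_prob, coupled_family)
        )
    return plants


def plant_te_catalog(
    genome: GenomeSpec,
    family_abundances: dict[str, int],
    plants: list[PlantSpec],
    seed: int,
) -> tuple[list[TERecord], list[bool]]:
    """Background TEs uniform over the genome plus coupled placements.

    Returns the catalog and one coupled/uncoupled flag per plant. For a
    coupled plant, one element of the coupled family is centered uniformly
    within ±1 kb of EACH anchor midpoint (the central 2 kb window on both
    sides). Elements poking past a chromosome end are clipped.
    """
    if any(not fam for fam in family_abundances):
        raise ValueError("family name empty")
    if any(n < 0 for n in family_abundances.values()):
        raise ValueError("family counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[TERecord] = []

    def _place(chrom: str, center: int, family: str) -> None:
        length = int(rng.integers(TE_LEN_MIN, TE_LEN_MAX + 1))
        size = genome.sizes[chrom]
        start = max(0, center - length // 2)
        end = min(size, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(TERecord(chrom, start, end, family, strand))

    total_len = sum(genome.lengths)
    for family in sorted(family_abundances):
        count = family_abundances[family]
        for _ in range(count):
            pos = int(rng.integers(0, total_len))
            for chrom, size in zip(genome.names, genome.lengths):
                if pos < size:
                    _place(chrom, pos, family)
                    break
                pos -= size

    coupled_flags: list[bool] = []
    for plant in plants:
        coupled = bool(rng.random() < plant.coupling_prob)
        coupled_flags.append(coupled)
        if coupled:
            for which in (1, 2):
                mid = plant.anchor_mid(which)
                offset = int(rng.integers(-COUPLE_HALF_WINDOW, COUPLE_HALF_WINDOW + 1))
                _place(plant.chrom, mid + offset, plant.coupled_family)
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.family))
    return records, coupled_flags


def _draw_positions(
    rng: np.random.Generator, bin_i: np.ndarray, bin_j: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """1-based read positions uniform within their bins, redrawn until the
    separation lands inside [MIN_SEP, MAX_SEP] (only edge-of-band bin pairs
    ever need a redraw)."""
    n = len(bin_i)
    pos1 = bin_i * BIN_SIZE + rng.integers(1, BIN_SIZE + 1, size=n)
    pos2 = bin_j * BIN_SIZE + rng.integers(1, BIN_SIZE + 1, size=n)
    bad = (pos2 - pos1 < MIN_SEP) | (pos2 - pos1 > MAX_SEP)
    while bad.any():
        k = int(bad.sum())
        pos1[bad] = bin_i[bad] * BIN_SIZE + rng.integers(1, BIN_SIZE + 1, size=k)
        pos2[bad] = bin_j[bad] * BIN_SIZE + rng.integers(1, BIN_SIZE + 1, size=k)
        bad = (pos2 - pos1 < MIN_SEP) | (pos2 - pos1 > MAX_SEP)
    return pos1, pos2


def generate_pairs_file(
    genome: GenomeSpec,
    plants: list[PlantSpec],
    background_rate: float,
    seed: int,
    out: str | Path,
) -> TruthTable:
    """Write a gzipped .pairs file; background Poisson per in-band bin pair
    plus ``focal_count`` reads inside each plant's center bin pair.

    Every emitted separation lies in [8, 40] kb; records are written
    position-sorted with pos1 <= pos2, 1-based. The gzip stream carries a
    zeroed mtime so identical seeds give byte-identical files.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    all_pos1: list[np.ndarray] = []
    all_pos2: list[np.ndarray] = []

    for chrom in genome.names:
        n_bins = genome.n_bins(chrom)
        if background_rate > 0:
            for d in range(MIN_SEP_BINS, MAX_SEP_BINS + 1):
                n_pairs = n_bins - d
                if n_pairs <= 0:
                    continue
                counts = rng.poisson(background_rate, size=n_pairs)
                nz = np.nonzero(counts)[0]
                if nz.size == 0:
                    continue
                bi = np.repeat(nz, counts[nz])
                p1, p2 = _draw_positions(rng, bi, bi + d)
                chroms.extend([chrom] * len(p1))
                all_pos1.append(p1)
                all_pos2.append(p2)

    rows = []
    for plant in plants:
        bi = np.full(plant.focal_count, plant.anchor1_bin)
        bj = np.full(plant.focal_count, plant.anchor2_bin)
        if plant.focal_count:
            p1, p2 = _draw_positions(rng, bi, bj)
            chroms.extend([plant.chrom] * len(p1))
            all_pos1.append(p1)
            all_pos2.append(p2)
        rows.append(
            {
                "chrom": plant.chrom,
                "anchor1_bin": plant.anchor1_bin,
                "anchor2_bin": plant.anchor2_bin,
                "focal_count": plant.focal_count,
                "coupling_prob": plant.coupling_prob,
                "coupled_family": plant.coupled_family,
            }
        )

    if all_pos1:
        pos1 = np.concatenate(all_pos1)
        pos2 = np.concatenate(all_pos2)
        chrom_arr = np.array(chroms)
        strand1 = np.where(rng.random(len(pos1)) < 0.5, "+", "-")
        strand2 = np.where(rng.random(len(pos1)) < 0.5, "+", "-")
        order = np.lexsort((pos2, pos1, chrom_arr))
    else:
        pos1 = pos2 = np.array([], dtype=int)
        chrom_arr = strand1 = strand2 = np.array([], dtype=str)
        order = np.array([], dtype=int)

    out = Path(out)
    with open(out, "wb") as raw, gzip.GzipFile(
        fileobj=raw, mode="wb", mtime=0
    ) as gz:
        header = ["## pairs format v1.0", "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2"]
        for chrom, size in zip(genome.names, genome.lengths):
            header.append(f"#chromsize: {chrom} {size}")
        lines = ["\n".join(header) + "\n"]
        for rank, idx in enumerate(order):
            lines.append(
                f"r{rank:07d}\t{chrom_arr[idx]}\t{pos1[idx]}\t{chrom_arr[idx]}"
                f"\t{pos2[idx]}\t{strand1[idx]}\t{strand2[idx]}\n"
            )
        gz.write("".join(lines).encode())

    return TruthTable(seed=seed, frame=pd.DataFrame(rows))


def simulate_dataset(
    out_dir: str | Path,
    genome: GenomeSpec,
    plants: list[PlantSpec],
    family_abundances: dict[str, int],
    background_rate: float,
    seed: int,
) -> SyntheticDataset:
    """Full fixture: pairs.gz + te.bed + chrom.sizes + truth.tsv.

    Distinct sub-seeds (derived from ``seed``) drive the contact and TE
    draws so the two sources of randomness stay independent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs_path = out_dir / "contacts.pairs.gz"
    te_path = out_dir / "te.bed"
    sizes_path = out_dir / "chrom.sizes"

    truth = generate_pairs_file(genome, plants, background_rate, seed, pairs_path)
    records, coupled = plant_te_catalog(
        genome, family_abundances, plants, seed=seed + 101
    )
    truth.frame["coupled"] = coupled
    write_te_bed(records, te_path)
    with open(sizes_path, "w") as fh:
        for chrom, size in zip(genome.names, genome.lengths):
            fh.write(f"{chrom}\t{size}\n")
    truth.to_tsv(out_dir / "truth.tsv")
    return SyntheticDataset(
        genome=genome,
        pairs_path=pairs_path,
        te_bed_path=te_path,
        chrom_sizes_path=sizes_path,
        truth=truth,
        te_records=records,
    )
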