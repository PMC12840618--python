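"""Focal hotspot calling and matched-coldfield search on binned contact maps.

A *hotspot* is a single 600 × 600 bp bin pair whose contact count stands out
focally from a low local background. Each candidate bin pair is judged on
the 5 × 5 grid of counts centered on it in the 2D contact matrix, with the
four grid corners excluded (21 cells retained). The call requires all of:

* center count >= 5,
* center >= 1.2 x the second-highest retained cell,
* median of the 20 retained non-center cells < 40% of the center.

Each hotspot is then matched to one *coldfield* — an extended
contact-depleted region found by sliding the 5 × 5 grid along the matrix
diagonal in 5-bin steps, 20 positions in each direction (±95 bins = ±57 kb
at 600 bp), and minimising the TMC score ``max^1.3 × median`` computed over
all 25 cells. Moving diagonally shifts both anchors by the same offset, so
the candidate keeps the hotspot's genomic separation and hence a comparable
distance-decay background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import BinnedContactMap

__all__ = [
    "Grid",
    "HotspotCall",
    "ColdfieldCall",
    "HotColdPair",
    "CORNER_CELLS",
    "extract_grid",
    "is_hotspot",
    "tmc",
    "find_coldfield",
    "call_all",
    "retained_cell_count",
    "search_span_bp",
]

log = logging.getLogger(__name__)

GRID_HALF = 2  # 5x5 grid
CORNER_CELLS = ((0, 0), (0, 4), (4, 0), (4, 4))


@dataclass(frozen=True)
class Grid:
    """5 x 5 count grid centered on a candidate bin pair.

    ``values[r, c]`` holds the count at bin pair
    ``(bin_i - 2 + r, bin_j - 2 + c)``; rows and columns are ordered by
    increasing bin index and missing sparse keys read as zero.
    """

    values: np.ndarray  # shape (5, 5), int

    @property
    def center(self) -> int:
        return int(self.values[GRID_HALF, GRID_HALF])

    def retained(self) -> np.ndarray:
        """The 21 cells used for hotspot evaluation (corners masked)."""
        mask = np.ones((5, 5), dtype=bool)
        for r, c in CORNER_CELLS:
            mask[r, c] = False
        return self.values[mask]

    def noncenter_retained(self) -> np.ndarray:
        """The 20 retained cells excluding the center."""
        mask = np.ones((5, 5), dtype=bool)
        for r, c in CORNER_CELLS:
            mask[r, c] = False
        mask[GRID_HALF, GRID_HALF] = False
        return self.values[mask]


def retained_cell_count() -> int:
    """Number of grid cells a hotspot is judged on (recomputed from the
    corner mask, not hard-coded)."""
    g = Grid(np.zeros((5, 5), dtype=int))
    return g.retained().size


def search_span_bp(step_bins: int = 5, n_positions: int = 20, bin_size: int = 600) -> int:
    """Maximum genomic displacement of the coldfield search, in bp."""
    return (n_positions - 1) * step_bins * bin_size


@dataclass(frozen=True)
class HotspotCall:
    chrom: str
    bin_i: int
    bin_j: int
    center_count: int
    second_max: int
    background_median: float


@dataclass(frozen=True)
class ColdfieldCall:
    chrom: str
    bin_i: int
    bin_j: int
    tmc: float
    offset_bins: int  # signed diagonal displacement from the hotspot


@dataclass(frozen=True)
class HotColdPair:
    hotspot: HotspotCall
    coldfield: ColdfieldCall


def extract_grid(
    cmap: BinnedContactMap, chrom: str, bin_i: int, bin_j: int
) -> Grid | None:
    """5x5 grid centered on (bin_i, bin_j); ``None`` when the center sits
    within 2 bins of a chromosome end (candidate skipped, not an error)."""
    if bin_i < GRID_HALF or bin_j < GRID_HALF:
        return None
    n_bins = cmap.n_bins(chrom)
    if n_bins is not None and (bin_i + GRID_HALF >= n_bins or bin_j + GRID_HALF >= n_bins):
        return None
    values = np.zeros((5, 5), dtype=int)
    get = cmap.counts.get
    for r in range(5):
        bi = bin_i - GRID_HALF + r
        for c in range(5):
            bj = bin_j - GRID_HALF + c
            key = (chrom, bi, bj) if bi <= bj else (chrom, bj, bi)
            values[r, c] = get(key, 0)
    return Grid(values)


def is_hotspot(
    grid: Grid,
    min_center: int = 5,
    excess: float = 1.2,
    median_frac: float = 0.4,
) -> bool:
    """The three focal criteria on the corner-masked grid.

    The "second-highest value" is the maximum over the 20 retained
    non-center cells, and the background median is taken over those same 20
    cells; center >= comparisons are inclusive, the median bound strict.
    """
    center = grid.center
    if center < min_center:
        return False
    others = grid.noncenter_retained()
    if center < excess * int(others.max()):
        return False
    return float(np.median(others)) < median_frac * center


def tmc(grid: Grid, exponent: float = 1.3) -> float:
    """Coldfield score ``max^exponent x median`` over ALL 25 cells.

    Low TMC marks an extended depleted region: both the brightest cell and
    the typical cell must be low. An all-zero grid scores 0.
    """
    m = int(grid.values.max())
    if m == 0:
        return 0.0
    return float(m) ** exponent * float(np.median(grid.values))


def grid_stats(grid: Grid) -> tuple[int, int, float]:
    """(center, second_max, background_median) for a hotspot call record."""
    others = grid.noncenter_retained()
    return grid.center, int(others.max()), float(np.median(others))


def find_coldfield(
    cmap: BinnedContactMap,
    hotspot: HotspotCall,
    step_bins: int = 5,
    n_positions: int = 20,
    exponent: float = 1.3,
) -> ColdfieldCall | None:
    """Minimise TMC over diagonal offsets ``d = ±k*step_bins``, k < n_positions.

    The search runs from the 0-offset position outward to ±57 kb at the
    defaults, but the 0-offset candidate coincides with the hotspot itself
    and is excluded from eligibility: a hotspot cannot serve as its own
    depleted control (on sparse maps its grid median is 0, which would
    otherwise make it TMC-minimal by the tie rule). Ties break toward the
    smallest |d|, then the negative offset. Returns ``None`` when every
    candidate falls off the chromosome ends (the caller drops such
    hotspots from paired output).
    """
    best: tuple[float, int, int] | None = None  # (tmc, |d|, d)
    best_call: ColdfieldCall | None = None
    offsets = [
        s * k * step_bins for k in range(1, n_positions) for s in (-1, 1)
    ]
    for d in offsets:
        bi, bj = hotspot.bin_i + d, hotspot.bin_j + d
        grid = extract_grid(cmap, hotspot.chrom, bi, bj)
        if grid is None:
            continue
        score = tmc(grid, exponent)
        key = (score, abs(d), d)
        if best is None or key < best:
            best = key
            best_call = ColdfieldCall(hotspot.chrom, bi, bj, score, d)
    return best_call


def call_all(
    cmap: BinnedContactMap,
    min_center: int = 5,
    excess: float = 1.2,
    median_frac: float = 0.4,
    step_bins: int = 5,
    n_positions: int = 20,
    exponent: float = 1.3,
) -> list[HotColdPair]:
    """Test every nonzero bin pair as a hotspot candidate and pair each call
    with its TMC-minimal coldfield. Deterministic given the map; no
    non-maximum suppression between adjacent calls."""
    pairs: list[HotColdPair] = []
    n_dropped = 0
    for chrom, bin_i, bin_j in sorted(cmap.counts):
        grid = extract_grid(cmap, chrom, bin_i, bin_j)
        if grid is None:
            continue
        if not is_hotspot(grid, min_center, excess, median_frac):
            continue
        center, second, med = grid_stats(grid)
        hot = HotspotCall(chrom, bin_i, bin_j, center, second, med)
        cold = find_coldfield(cmap, hot, step_bins, n_positions, exponent)
        if cold is None:
            n_dropped += 1
            continue
        pairs.append(HotColdPair(hot, cold))
    if n_dropped:
        log.info("call_all: dropped %d hotspot(s) with no valid coldfield", n_dropped)
    return pairs
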