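"""Sliding-window homotypic/heterotypic TE pairing at contact anchors.

Around each contact anchor (hotspot or matched coldfield), the flanking
±11 kb is scanned with 21 sliding windows of 2 kb width at 50% overlap
(window centers every 1 kb from −10 kb to +10 kb; the center window covers
−1 kb to +1 kb). A TE belongs to a window when its element center falls
inside the window, bounds inclusive — an element on a shared boundary
belongs to both windows.

For each contact and window index, the families present at anchor 1 are
paired with the families present at anchor 2: the same family on both sides
is a homotypic pairing, different families a heterotypic pairing. Counting
is presence-based by default — one increment per contact per window per
unordered family pair, regardless of copy number — which keeps Alu-dense
windows from dominating; element-pair product counting is available as an
option.

Per family, three summary metrics over the central window:

* hot/cold ratio       — homotypic counts at hotspots / at coldfields;
* heterotypic ratio    — same, over pairings with any *other* family;
* specificity index    — hot/cold ratio divided by heterotypic ratio,
  the preference for same-family pairing net of local TE density.

Also derived here: the family × family specificity matrix (hot/cold count
ratio per family pair, sorted by its diagonal), the head–head / head–tail
strand-orientation ratio of homotypic pairs (opposite strands = head–head),
and the Pearson correlation between family age and homotypic enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .te_catalog import TERecord

__all__ = [
    "WindowSpec",
    "PairingTable",
    "FamilyMetrics",
    "SpecificityMatrix",
    "make_windows",
    "assign_windows",
    "count_pairings",
    "family_metrics",
    "all_family_metrics",
    "specificity_matrix",
    "orientation_ratio",
    "age_correlation",
    "DEFAULT_AGES_MYR",
    "HOT",
    "COLD",
]

log = logging.getLogger(__name__)

HOT = "hot"
COLD = "cold"
CONTEXTS = (HOT, COLD)


@dataclass(frozen=True)
class WindowSpec:
    """21 windows of ``width`` bp whose centers step by ``step`` bp,
    spanning offsets −10 kb … +10 kb (edges −11 kb … +11 kb)."""

    width: int = 2_000
    step: int = 1_000
    offsets: tuple[int, ...] = tuple(range(-10_000, 10_001, 1_000))

    @property
    def n_windows(self) -> int:
        return len(self.offsets)

    @property
    def center_index(self) -> int:
        return self.offsets.index(0)

    def bounds(self, index: int) -> tuple[int, int]:
        """Inclusive [lo, hi] of window ``index``, relative to the anchor."""
        half = self.width // 2
        return self.offsets[index] - half, self.offsets[index] + half


def make_windows(width: int = 2_000, step: int = 1_000, flank: int = 11_000) -> WindowSpec:
    half = width // 2
    offsets = tuple(range(-(flank - half), flank - half + 1, step))
    return WindowSpec(width=width, step=step, offsets=offsets)


@dataclass
class PairingTable:
    """Accumulated pairing counts.

    ``counts[(context, famA, famB, window_index)]`` with famA <= famB
    lexicographically; homotypic entries have famA == famB. Head-head /
    head-tail tallies are element-level strand classifications of homotypic
    pairs (opposite strands = head-head).
    """

    windows: WindowSpec = field(default_factory=WindowSpec)
    counts: dict[tuple[str, str, str, int], int] = field(default_factory=dict)
    n_contacts: dict[str, int] = field(default_factory=lambda: {HOT: 0, COLD: 0})
    head_head: dict[str, int] = field(default_factory=lambda: {HOT: 0, COLD: 0})
    head_tail: dict[str, int] = field(default_factory=lambda: {HOT: 0, COLD: 0})

    def get(self, context: str, fam_a: str, fam_b: str, window: int) -> int:
        a, b = sorted((fam_a, fam_b))
        return self.counts.get((context, a, b, window), 0)

    def families(self) -> list[str]:
        fams: set[str] = set()
        for _, a, b, _ in self.counts:
            fams.add(a)
            fams.add(b)
        return sorted(fams)

    def family_total(self, family: str) -> int:
        """Total pairing involvement of a family (all contexts/windows)."""
        return sum(
            n for (_, a, b, _), n in self.counts.items() if family in (a, b)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"context": ctx, "family_a": a, "family_b": b, "window": w, "count": n}
            for (ctx, a, b, w), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["context", "family_a", "family_b", "window", "count"]
        )

    def homotypic_profile(self, context: str, family: str | None = None) -> np.ndarray:
        """Homotypic counts across the 21 windows (one family or summed)."""
        out = np.zeros(self.windows.n_windows, dtype=float)
        for (ctx, a, b, w), n in self.counts.items():
            if ctx == context and a == b and (family is None or a == family):
                out[w] += n
        return out


def assign_windows(
    tes: list[TERecord], anchor_pos: int, spec: WindowSpec
) -> dict[int, list[tuple[str, str]]]:
    """Map window index -> [(family, strand), ...] for TEs near an anchor.

    Membership by element center with inclusive bounds; with 50%-overlapping
    windows an element generically lands in two windows (three when its
    center sits exactly on a shared boundary).
    """
    out: dict[int, list[tuple[str, str]]] = {}
    for te in tes:
        rel = te.center - anchor_pos
        for i in range(spec.n_windows):
            lo, hi = spec.bounds(i)
            if lo <= rel <= hi:
                out.setdefault(i, []).append((te.family, te.strand))
    return out


def count_pairings(
    anchor1_windows: dict[int, list[tuple[str, str]]],
    anchor2_windows: dict[int, list[tuple[str, str]]],
    context: str,
    table: PairingTable,
    product_counting: bool = False,
) -> PairingTable:
    """Accumulate one contact's pairings into ``table``.

    Presence-based (default): for each window index shared by both anchors,
    each unordered family pair with one member present on each side gains
    one count. Product counting instead adds the number of element pairs
    realising the family pair. Symmetric in the two anchors either way.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    table.n_contacts[context] += 1
    for w in set(anchor1_windows) & set(anchor2_windows):
        side1 = anchor1_windows[w]
        side2 = anchor2_windows[w]
        if product_counting:
            pair_counts: dict[tuple[str, str], int] = {}
            for fam1, _ in side1:
                for fam2, _ in side2:
                    a, b = sorted((fam1, fam2))
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
            for (a, b), n in pair_counts.items():
                key = (context, a, b, w)
                table.counts[key] = table.counts.get(key, 0) + n
        else:
            fams1 = {f for f, _ in side1}
            fams2 = {f for f, _ in side2}
            pairs = {tuple(sorted((f1, f2))) for f1 in fams1 for f2 in fams2}
            for a, b in pairs:
                key = (context, a, b, w)
                table.counts[key] = table.counts.get(key, 0) + 1
        # strand orientation of homotypic element pairs (element-level)
        for fam1, s1 in side1:
            for fam2, s2 in side2:
                if fam1 == fam2:
                    if s1 != s2:
                        table.head_head[context] += 1
                    else:
                        table.head_tail[context] += 1
    return table


@dataclass(frozen=True)
class FamilyMetrics:
    family: str
    hot_cold_ratio: float
    heterotypic_ratio: float
    specificity_index: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.hot_cold_ratio) and math.isfinite(
            self.specificity_index
        )


def _het_count(table: PairingTable, context: str, family: str, window: int) -> int:
    total = 0
    for (ctx, a, b, w), n in table.counts.items():
        if ctx == context and w == window and a != b and family in (a, b):
            total += n
    return total


def family_metrics(
    table: PairingTable, family: str, window: int | None = None
) -> FamilyMetrics:
    """The three per-family metrics over the central window.

    A zero coldfield denominator leaves the affected metric(s) NaN; such
    families are excluded from downstream correlation and clustering.
    """
    if family not in table.families():
        raise KeyError(f"family {family!r} absent from pairing table")
    w = table.windows.center_index if window is None else window
    hot_homo = table.get(HOT, family, family, w)
    cold_homo = table.get(COLD, family, family, w)
    hot_het = _het_count(table, HOT, family, w)
    cold_het = _het_count(table, COLD, family, w)
    hc = hot_homo / cold_homo if cold_homo else float("nan")
    het = hot_het / cold_het if cold_het else float("nan")
    spec = hc / het if het and math.isfinite(hc) and math.isfinite(het) else float("nan")
    if not math.isfinite(hc):
        log.debug("family %s: hot/cold ratio undefined (cold homotypic = 0)", family)
    return FamilyMetrics(family, hc, het, spec)


def all_family_metrics(
    table: PairingTable, families: list[str] | None = None, window: int | None = None
) -> pd.DataFrame:
    fams = table.families() if families is None else families
    rows = [family_metrics(table, f, window).__dict__ for f in fams]
    return pd.DataFrame(
        rows, columns=["family", "hot_cold_ratio", "heterotypic_ratio", "specificity_index"]
    )


@dataclass
class SpecificityMatrix:
    """Symmetric family x family hot/cold pairing-count ratios (central
    window), rows/columns sorted by descending diagonal."""

    families: list[str]
    values: pd.DataFrame  # square, index == columns == families

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.families)


def specificity_matrix(
    table: PairingTable, top_k: int = 30, window: int | None = None
) -> SpecificityMatrix:
    """Entry (A, B) = hot count(A,B) / cold count(A,B) in the central
    window, over the ``top_k`` families by total pairing counts; undefined
    cells (cold = 0) are NaN."""
    w = table.windows.center_index if window is None else window
    fams = sorted(
        table.families(), key=lambda f: (-table.family_total(f), f)
    )[:top_k]
    mat = pd.DataFrame(np.nan, index=fams, columns=fams)
    for a in fams:
        for b in fams:
            hot = table.get(HOT, a, b, w)
            cold = table.get(COLD, a, b, w)
            if cold:
                mat.loc[a, b] = hot / cold
    order = (
        pd.Series(np.diag(mat), index=fams)
        .sort_values(ascending=False, kind="stable")
        .index.tolist()
    )
    mat = mat.loc[order, order]
    return SpecificityMatrix(families=order, values=mat)


def orientation_ratio(table: PairingTable, context: str | None = None) -> float:
    """head-head / head-tail count ratio of homotypic element pairs.

    Head-head = the two elements on opposite strands (facing), head-tail =
    same strand (tandem). NaN (flagged) when no head-tail pair exists.
    """
    ctxs = CONTEXTS if context is None else (context,)
    hh = sum(table.head_head[c] for c in ctxs)
    ht = sum(table.head_tail[c] for c in ctxs)
    if ht == 0:
        log.warning("orientation_ratio undefined: no head-tail pairs")
        return float("nan")
    return hh / ht


# Family ages in Myr. MIR ~130 and Alu ~50 anchor the scale; the remaining
# entries are conventional literature estimates, editable via a TSV table.
DEFAULT_AGES_MYR: dict[str, float] = {
    "MIR": 130.0,
    "MIRb": 130.0,
    "MIRc": 130.0,
    "MIR3": 130.0,
    "L2": 140.0,
    "L2a": 140.0,
    "L2b": 140.0,
    "L2c": 140.0,
    "L1": 100.0,
    "ERVL": 70.0,
    "Alu": 50.0,
    "AluY": 25.0,
    "AluSx": 45.0,
    "AluJb": 60.0,
    "SVA": 13.0,
}


def age_correlation(
    metrics: pd.DataFrame,
    ages: dict[str, float] | None = None,
    metric: str = "hot_cold_ratio",
) -> tuple[float, int]:
    """Pearson r between family age (Myr) and a homotypic metric.

    Families lacking an age or a defined metric are dropped; fewer than 3
    usable families raises, zero age variance yields NaN (flagged).
    """
    ages = DEFAULT_AGES_MYR if ages is None else ages
    rows = metrics.dropna(subset=[metric])
    rows = rows[rows["family"].isin(ages)]
    if len(rows) < 3:
        raise ValueError("age correlation needs >= 3 families with age and metric")
    x = np.array([ages[f] for f in rows["family"]], dtype=float)
    y = rows[metric].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("age_correlation undefined: zero variance")
        return float("nan"), len(rows)
    r, _ = stats.pearsonr(x, y)
    return float(r), len(rows)
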