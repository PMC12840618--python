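# Methods

## Model and procedure

`tepair` analyses chromatin-contact read pairs (`.pairs` text format) at
kilobase resolution. Only intra-chromosomal contacts with separations in
[8 000, 40 000] bp are used — local loops beyond immediate-neighbour
distance decay — and both band bounds are treated as inclusive. Contacts
are accumulated on a 0-based 600 bp bin lattice with bin index
`floor((pos − 1)/bin_size)` over the 1-based coordinate stream; the lattice
phase is part of the method's identity (the misbinning control below depends
on it).

Large files are thinned with a systematic sampling plan over raw data
lines (skip an initial block, then alternating take/skip cycles; defaults
1 M / 800 K / 2.5 M). Sampling indexes raw read pairs, not retained
contacts, so the same plan always selects the same physical reads
regardless of downstream filtering.

**Hotspots** are single bin pairs whose count stands out focally. The 5×5
count grid centred on a candidate is evaluated with its four corners
excluded (21 cells): the call requires centre ≥ 5, centre ≥ 1.2× the
highest retained non-centre cell, and median of the 20 retained non-centre
cells < 0.4× the centre. The `≥` comparisons are inclusive and the median
bound strict, mirroring the glyphs of the published criteria. The
"second-highest" and the background median are both computed over the 20
non-centre retained cells: the criterion contrasts a focal centre against
its local background, so the centre itself is excluded from that
background. Candidates within 2 bins of a chromosome end are skipped. No
non-maximum suppression is applied between adjacent calls.

**Coldfields** are extended contact-depleted regions matched to each
hotspot by sliding the 5×5 grid along the matrix diagonal (both anchors
shifted equally, preserving separation and hence distance-decay) in 5-bin
steps, up to 19 steps in each direction: a ±95-bin = ±57 kb corridor at
600 bp. Each candidate is scored with `TMC = max^1.3 × median` over all
25 cells — the corner rule applies only to hotspot evaluation — and the
minimum wins; ties break toward the smallest |offset|, then the negative
offset. The 1.3 exponent is a fixed constant of the procedure, exposed in
the configuration. The 0-offset position coincides with the hotspot itself
and is excluded from eligibility: a hotspot cannot serve as its own
depleted control, and on sparse maps its grid median is 0, which would
otherwise make it TMC-minimal by the tie rule and collapse every hot/cold
comparison to identity. Hotspots whose entire corridor falls off the
chromosome are dropped from paired output (logged).

**TE pairing.** TE annotations (BED-like TSV; 0-based half-open; family
and strand) are bucketed in 10 kb bins; flank queries return elements
whose *centre* lies within ±11 kb of an anchor (bin midpoint), bounds
inclusive. Membership by centre is used consistently for flank queries
and window assignment. Each anchor's elements are assigned to 21 sliding
2 kb windows at 50 % overlap (window centres every 1 kb from −10 to
+10 kb); an element on a shared window boundary belongs to every window
that contains it, so a centre generically falls in two windows and in
three exactly on boundaries. Window *i* at anchor 1 is compared only with
window *i* at anchor 2 — a single distance axis, no cross-window
combinations.

Counting is presence-based: per contact, per window, per unordered family
pair, one increment when one member of the pair is present on each side.
This makes the statistic robust to copy-number inflation in Alu-dense
windows; per-element product counting is available behind a configuration
switch (`product_counting`). Family identity is the verbatim annotation
name; an optional map collapses names into superfamilies. The head–head /
head–tail orientation ratio is element-level: a homotypic element pair on
opposite strands counts as head–head (facing), same strands as head–tail
(tandem) — a definitional choice, since either convention is defensible.

Per family, over the centre window: hot/cold homotypic ratio, heterotypic
ratio (summing pairings of that family with any *different* partner), and
the specificity index (their quotient). Zero denominators leave a metric
undefined (NaN, flagged); undefined families are excluded pairwise from
correlations and dropped from clustering rather than imputed. The
family×family specificity matrix holds hot/cold count ratios per pair over
the centre window, restricted to the top-K families by total pairing
counts (default 30) and sorted by descending diagonal. Age correlation is
a plain Pearson r between family age (Myr) and the homotypic hot/cold
ratio; the bundled age table anchors MIR at ~130 Myr and Alu at ~50 Myr,
with the remaining entries conventional literature estimates that users
can replace via TSV.

**Reproducibility** across datasets uses Pearson correlation of per-family
ratio vectors (≥3 shared defined families required) and average-linkage
hierarchical clustering on Euclidean distances between family profiles
(raw ratios by default; log2 optional).

## The misbinning negative control

The control asks whether the central-window signal is genuinely anchored
to genomic coordinates or is an artifact of the pipeline. Hotspots and
coldfields are called once on the correct 600 bp lattice; the pairing
phase is then run twice, once converting bin indices to genomic anchor
positions with the correct bin size and once with a deliberately wrong
580 bp size (`pos = bin × 580 + 290`). The coordinate error grows as
20 bp × bin index — from ~2 kb to >100 kb across a megabase-scale
chromosome — so anchors are effectively reshuffled genome-wide and any
genuine signal must flatten to a hot/cold ratio of 1.

A second mode (`mode="rebin"`) re-runs the *entire* pipeline, binning
included, at 580 bp. This is deliberately offered but is the weaker
control: re-binning shifts a surviving focal call by at most ~±300 bp,
well inside the ±1 kb centre window, so planted signal is attenuated
(measured centre-window ratios drop roughly by half) rather than
eliminated. The coordinate-conversion mode is the default because its
null is exact.

## The synthetic-data generator

The generator manufactures the study conditions the analysis assumes, and
nothing more:

- **Genome**: named toy chromosomes (`chrS1`, …); a chromosome must be
  ≥200 kb so one hotspot fits with its ±57 kb search corridor and ±11 kb
  flanks.
- **Contacts**: per 600 bp bin pair with lattice separation inside the
  8–40 kb band, background counts are homogeneous Poisson with a given
  mean; read positions are uniform within their bins, redrawn at the band
  edges so every emitted separation stays inside the band. Each planted
  spot adds `focal_count` reads inside one chosen bin pair. Records are
  written 1-based, position-sorted, with a zeroed gzip mtime: identical
  seeds give byte-identical files. The homogeneous Poisson null is a
  modelling choice — under it, together with uniform TE placement, the
  expected hot/cold pairing ratio is exactly 1, which is what makes the
  calibration experiments interpretable.
- **TEs**: background elements placed uniformly with lengths uniform in
  [150, 6 000] bp (Alu-like through L1-like) and fair-coin strands. With
  probability `coupling_prob` a plant is *coupled*: one element of the
  chosen family is centred uniformly within ±1 kb of each anchor midpoint
  (the centre window on both sides). A truth table records every plant and
  coupling decision.
- **Layout**: planted spots are spaced ≥12 bins apart in their first
  anchor. This keeps distinct plants' 5×5 grids disjoint and — because the
  nearest eligible coldfield sits 5 bins (3 kb) away — keeps one plant's
  coupled elements out of the centre window of any neighbouring plant's
  coldfield anchors, so planted coupling cannot leak into coldfield
  baselines.

All randomness flows through explicit integer seeds; there is no global
RNG state.

What the generator does **not** emulate: distance-dependent contact decay,
chromatin compartments or diffuse high-contact fields, fragmentation
chemistry (MNase vs restriction digestion), duplicate reads, trans
contacts, mappability structure, or realistic TE length/strand/clustering
statistics. Passing the validation experiments therefore shows that the
*pipeline* measures planted coupling correctly under a clean null — not
that any particular biological dataset will show such coupling.

## Validation experiments and problem sizes

The experiments in `tepair.experiments` fix the study conditions
(fixture sizes chosen for clear signal-to-noise at single-CPU scale):

- *Planted recovery*: 10 spots of 10 reads on an empty background, 1 Mb
  genome — calls must equal the truth table exactly.
- *Null calibration*: 550 uncoupled spots, 5 Mb genome, background rate
  0.05; per family the central hot count given hot+cold is Binomial(n, ½)
  under the null, and each family must sit inside the central 99 %
  binomial interval.
- *Dose response*: 400 spots at coupling 0 / 0.25 / 0.5 / 1 on a 6 Mb
  genome; the coupled family's centre-window ratio must increase strictly.
  The 6 Mb genome keeps slot occupancy low enough that coupled anchors of
  different plants rarely coincide with coldfield anchors.
- *Misbin control*: 400 fully coupled spots, 4 Mb genome; correct-arm
  ratio ≫ 1, wrong-coordinate arm ≈ 1 with a flat profile.
- *Profile shape*: 200 fully coupled spots; the homotypic count profile
  across the 21 windows must peak at offset 0.

Six background families at ~0.5 elements per family per 2 kb window give
hg38-like central-window occupancy. `scripts/acceptance.py` re-runs all of
the above from scratch for a given seed and writes the measured numbers.

## Known limitations

- Coldfields on very sparse synthetic maps are usually the nearest tied
  zero-TMC candidate (offset −5 bins), so the synthetic "cold" flank
  profile is essentially the hot profile displaced by 3 kb; only the
  centre window is guaranteed uncontaminated by construction. On dense
  real data TMC is informative and coldfields spread over the corridor.
- Presence-based counting saturates: once every hot pair has the coupled
  family on both sides, the hot count equals the number of pairs and
  further coupling cannot raise it.
- No statistical significance model is attached to hotspot calls or ratio
  differences; the package reports effect sizes and calibrated nulls only.
- Age assignments for repeat families other than MIR and Alu are coarse
  defaults, intended for the correlation's sign and ordering rather than
  precise dating.
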