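# tepair

Homotypic transposable-element (TE) pairing at focal chromatin contacts.

Over half the human genome is transposable-element sequence, and TE families
form homotypic clusters in nuclear space. `tepair` asks a sharper question at
kilobase scale: when two loci touch (a Micro-C/Hi-C contact), does the same TE
family sit on *both* sides of the contact more often than expected — and does
that preference vanish in contact-depleted regions? The package is aimed at
regulatory-genomics analysts working with `.pairs`-format contact data and
BED-like repeat annotations, and at anyone who wants to stress-test this kind
of anchor-level enrichment analysis on synthetic data with known truth.

## The method

Working on intra-chromosomal read pairs at separations of 8–40 kb, binned on a
600 bp lattice:

1. **Hotspot calling.** Each nonzero bin pair is judged on the 5×5 grid of
   counts centred on it, with the four grid corners excluded (21 cells kept).
   A bin pair is a *hotspot* when its centre count `c` satisfies
   `c ≥ 5`, `c ≥ 1.2·max(neighbours)`, and `median(neighbours) < 0.4·c`,
   where the 20 retained non-centre cells are the neighbours — a singular
   focal peak on a low local background.
2. **Coldfield matching.** For each hotspot the grid slides along the matrix
   diagonal in 5-bin steps, 20 positions in each direction (±95 bins = ±57 kb),
   preserving anchor separation. Each candidate is scored with
   `TMC = max^1.3 × median` over all 25 cells; the minimum-TMC position is the
   matched *coldfield* — an extended contact-depleted control region.
3. **TE pairing.** Around each anchor (bin midpoint), TEs within ±11 kb are
   collected and assigned by element centre to 21 sliding windows of 2 kb
   width at 50 % overlap (centre window −1…+1 kb). For every window, the
   family sets at the two anchors are crossed: same family on both sides is a
   *homotypic* pairing, different families *heterotypic*. Per family `f`,
   over the centre window:

   - hot/cold ratio `R_f = hom_hot(f) / hom_cold(f)`
   - heterotypic ratio `H_f = het_hot(f) / het_cold(f)`
   - specificity index `S_f = R_f / H_f`

   plus a family×family specificity matrix, a head–head/head–tail strand
   orientation ratio, and the Pearson correlation of `R_f` with family age.
4. **Controls and reproducibility.** Cross-dataset Pearson correlation of
   ratio vectors, average-linkage/Euclidean family clustering, and a
   misbinning negative control that recomputes anchor coordinates with a
   deliberately wrong 580 bp bin size — reshuffling anchors genome-wide and
   erasing any genuine lattice-anchored signal.

A synthetic-data generator produces `.pairs` files with Poisson background,
planted focal spots, and tunable same-family TE coupling at the planted
anchors, with a truth table for recovery tests.

## Worked example

`examples/02_pairing_metrics.py` plants 100 focal spots on a 2 Mb toy
chromosome, each coupled to a MIRb element within ±1 kb of both anchors, and
runs the full pipeline:

```
hotspot/coldfield pairs: 100

per-family metrics (central 2 kb window):
family  hot_cold_ratio  heterotypic_ratio  specificity_index
 AluSx           0.929              1.181              0.786
  AluY           1.462              1.119              1.306
   L1M           1.353              1.248              1.084
   L2a           0.769              1.177              0.653
  MIRb           4.167              1.675              2.488
  MIRc           0.750              1.084              0.692

head-head / head-tail orientation ratio: 1.022
```

The planted family (MIRb) shows a central-window homotypic hot/cold ratio of
4.17 and tops the specificity diagonal, while the five uncoupled families
scatter around 1 — exactly the signature the analysis is built to detect. The
orientation ratio sits near 1 because planted strands are fair coins. The
other examples demonstrate hotspot recovery, null calibration and dose
response, the misbinning control, and replicate correlation/clustering.

A command-line interface mirrors the stages:

```sh
tepair simulate --out-dir sim --seed 1
tepair bin --pairs sim/contacts.pairs.gz --chrom-sizes sim/chrom.sizes --out map.tsv
tepair callspots --map map.tsv --out hotcold.tsv
tepair pairing --pairs hotcold.tsv --te sim/te.bed --out-dir results/
tepair control --pairs sim/contacts.pairs.gz --te sim/te.bed \
    --chrom-sizes sim/chrom.sizes --out control.tsv
tepair demo --seed 1 --out-dir demo/
```

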