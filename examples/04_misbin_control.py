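"""Misbinning negative control.

The pairing phase is run twice on identical hotspot/coldfield calls: once
with correct 600 bp anchor coordinates and once converting bin indices
with a deliberately wrong 580 bp bin size, which shifts each anchor by
20 bp x bin index and thereby reshuffles anchors genome-wide. A genuine
lattice-anchored signal must survive the first and vanish in the second.
"""

from tepair.experiments import misbin_experiment

res = misbin_experiment(seed=1)
print(f"central hot/cold ratio, correct 600 bp coordinates : {res.central_ratio_standard:.3f}")
print(f"central hot/cold ratio, wrong 580 bp coordinates   : {res.central_ratio_misbinned:.3f}")
print("\nhomotypic window profile (hot context):")
print("offset_kb  correct  misbinned")
for off, a, b in zip(res.offsets, res.hot_profile_standard, res.hot_profile_misbinned):
    marker = "  <- contact point" if off == 0 else ""
    print(f"{off/1000:9.0f}  {a:7.0f}  {b:9.0f}{marker}")
# The correct arm peaks sharply at offset 0; the misbinned arm is flat
# with a ratio near 1 — the focal signal is genomic, not a pipeline artifact.
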