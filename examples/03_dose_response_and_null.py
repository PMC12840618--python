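"""Null calibration and coupling dose response.

With no planted coupling every family's homotypic hot/cold ratio should
sit at 1 up to binomial sampling noise; raising the coupling probability
of one family should raise that family's ratio monotonically.
"""

from tepair.experiments import dose_response, null_calibration

null = null_calibration(seed=1)
print("null calibration (coupling_prob = 0, %d hot/cold pairs):" % null.attrs["n_pairs"])
print(null.round(3).to_string(index=False))

dr = dose_response(seed=1)
print("\ndose response of the coupled family (MIRb):")
print(dr.round(3).to_string(index=False))
# 'ratio' should increase strictly down the rows: more coupling, more
# homotypic pairing at hotspots relative to matched coldfields.
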