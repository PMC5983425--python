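"""Break-even staff time saving factor.

The incremental cost falls linearly in the fraction s of frozen-section
waiting time whose staff cost is actually avoided. Two thresholds matter:
where the point estimate crosses zero, and where the saving becomes
statistically significant (the PSA's 97.5th percentile reaches zero).
"""

from ifmiecon import load_parameters, threshold_staff_factor

params = load_parameters()

pt = threshold_staff_factor(params, "point")
sig = threshold_staff_factor(params, "significance")

print(f"point break-even:        s* = {pt.s_star:.3f}")
print(f"significance break-even: s* = {sig.s_star:.3f} "
      f"(n = {sig.n_draws:,} draws, tol {sig.tol})")
print("Above the first threshold IFMI saves costs in expectation; above the "
      "second the saving is significant at the 5% level. The base-case "
      "factor of 0.64 clears the first comfortably but sits near the second.")
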