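"""Full pipeline: simulate a dose series, segment, measure, fit.

Each nucleus fuses with probability logistic(µ + c·dose + u_g); the
rendered scenes are segmented, the per-frame fused/total nucleus
counts measured, and a dose-slope logistic model with a random group
intercept fitted to the measurements.  The fitted slope recovers the
programmed value.
"""

from myoquant.validation import dose_response_recovery

res = dose_response_recovery(seed=1, mu=-1.2, c=0.5,
                             doses=(0.0, 1.0, 2.0, 3.0), n_groups=3)
print(f"programmed dose coefficient: {res['c_true']:+.3f} log-odds per unit")
print(f"fitted:  {res['c_hat']:+.3f} ± {res['se']:.3f}")
print(f"z vs truth: {res['z_vs_truth']:+.2f}  "
      f"(sign correct: {res['sign_correct']})")
print(f"scenes rendered and segmented: {res['n_scenes']}")
# |z| < 2 means the estimate is within two standard errors of the
# programmed effect — the whole image-analysis chain preserves the
# dose–response signal.
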