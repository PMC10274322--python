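"""Reproduce the constant-coefficient-offset agreement signature.

Two RSS programs that use different solubility products disagree in a very
particular way: regressing one program's output on the other's gives a slope
equal to the Ksp ratio with r-squared = 1, while Lin's concordance
correlation coefficient (which penalises bias) drops well below the Pearson
correlation.  Here a second "program" is emulated by dividing the struvite
Ksp by 3 and the full four-part agreement suite is run on 200 synthetic
canine samples.
"""

from urisat import (
    agreement_report,
    compute_rss,
    generate_panels,
    load_constants,
    make_series,
    perturb_constants,
    preset,
)

base = load_constants("default")
control = perturb_constants(base, salt_scale={"struvite": 3.0})  # Ksp / 3

panels = generate_panels(preset("canine"), 200, seed=42)
new = [compute_rss(p, base).rss("struvite") for p in panels]
ctl = [compute_rss(p, control).rss("struvite") for p in panels]

rep = agreement_report(make_series(new, ctl))
print(f"n pairs          : {rep.n}")
print(f"mean diff (se)   : {rep.mean_diff:.3f} ({rep.se_diff:.3f})   [Control - New]")
print(f"slope (95% CI)   : {rep.slope:.4f} ({rep.slope_ci95[0]:.4f}, {rep.slope_ci95[1]:.4f})")
print(f"r-squared        : {rep.r2:.6f}")
print(f"Lin's CCC        : {rep.ccc:.4f}")
print(f"BA 2SD limits    : ({rep.ba['limits_2sd'][0]:.3f}, {rep.ba['limits_2sd'][1]:.3f})")

print(
    "\nThe slope recovers the Ksp factor (3) exactly and r2 = 1: the two\n"
    "programs rank every sample identically.  The depressed CCC shows they\n"
    "are nevertheless not interchangeable — exactly the pattern produced by\n"
    "two real RSS programs with different coefficient tables."
)
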