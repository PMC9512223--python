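"""Estimate cohort-mean forces on ramps that were never measured.

The empirical engine returns the published cohort means bit-exactly at
the four measured ramps (0/5/10/15 deg), interpolates linearly between
them, and extrapolates a least-squares line through all four anchors for
any new ramp up to the 70 deg gate.
"""

from hipforce import grf_empirical, jrf_empirical, validate_ramp

for theta in (0, 7.5, 15, 40, 70):
    jrf = jrf_empirical(600.0, validate_ramp(theta))
    grf_m = grf_empirical("male", validate_ramp(theta))
    print(
        f"ramp {theta:>5.1f}°:  JRF = {jrf.empirical_value:7.2f} {jrf.unit}"
        f"   GRF(male) = {grf_m:7.2f} N"
    )

print(
    "\n0/15° rows are stored published anchors; 7.5° is a linear"
    " interpolation; 40° and 70° are least-squares extrapolations."
)
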