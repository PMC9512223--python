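"""Decompose the ground reaction force on level ground and on inclines.

The GRF stays perpendicular to the walking surface with magnitude equal
to body weight, so steepening the ramp trades vertical support for a
backward-pointing (negative) anteroposterior component, and the direction
angle flips from +90 deg to a negative principal value.
"""

from hipforce import grf_mechanistic, validate_ramp

WEIGHT_N = 600.0

for theta in (0, 15, 30, 70):
    res = grf_mechanistic(WEIGHT_N, validate_ramp(theta))
    v = res.vector
    print(
        f"ramp {theta:>2}°:  ap = {v.ap:8.2f} N   vert = {v.vert:7.2f} N   "
        f"|GRF| = {v.resultant_3d:6.1f} N   alpha = {res.alpha:7.2f}°"
    )

print(
    "\nThe resultant equals body weight on every ramp; only its"
    " orientation changes, and alpha is negative on every true incline."
)
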