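"""Simulate a synthetic 40-subject cohort and summarise it.

Twenty subjects per gender with gender-stratified body masses walk the
four measured ramps; each published cohort mean is perturbed with
unit-mean lognormal noise of CV 0.135 (matched to the published
dispersion), then summarised as mean (+/- SD) per gender x ramp cell.
"""

from hipforce import (
    CohortConfig,
    generate_cohort,
    simulate_observations,
    summarize,
    validate_ramp,
)

config = CohortConfig(random_seed=1)
cohort = generate_cohort(config)
print(f"generated {len(cohort)} subjects "
      f"(first: {cohort[0].subject_id}, {cohort[0].body_mass_kg:.1f} kg)\n")

observations = simulate_observations(
    cohort, [validate_ramp(t) for t in (0, 5, 10, 15)], "empirical", config
)
print(summarize(observations).to_text())
print(
    "Cell means scatter around the published anchors (119.4 ... 149) with"
    " SD/mean ratios near the configured 0.135; rerunning with the same"
    " seed reproduces the table bit-for-bit."
)
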