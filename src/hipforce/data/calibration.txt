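# hipforce calibration anchors, version 1
# Per-ramp cohort mean hip joint reaction force (printed unit "BW") and
# total ground reaction force at the hip (newtons) with sample SDs, for
# the four experimentally measured ramp inclinations (degrees).
# Format: one record per line, whitespace separated.
#   jrf_anchor <ramp_deg> <mean>
#   jrf_sd     <ramp_deg> <sd>
#   grf_anchor <gender> <ramp_deg> <mean>
#   grf_sd     <gender> <ramp_deg> <sd>
#   policy     <name>
jrf_anchor 0 119.4
jrf_anchor 5 129.5
jrf_anchor 10 138.6
jrf_anchor 15 149
jrf_sd 0 16.1
jrf_sd 5 17.4
jrf_sd 10 18.2
jrf_sd 15 19.6
grf_anchor male 0 509.49
grf_anchor female 0 518.64
grf_anchor male 5 499.87
grf_anchor female 5 504.25
grf_anchor male 10 527.7
grf_anchor female 10 517.57
grf_anchor male 15 549.58
grf_anchor female 15 552.24
grf_sd male 0 34.69
grf_sd female 0 5.41
grf_sd male 5 25.3
grf_sd female 5 22.49
grf_sd male 10 27.38
grf_sd female 10 15.58
grf_sd male 15 3.95
grf_sd female 15 19.24
policy linear_interp_then_least_squares
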