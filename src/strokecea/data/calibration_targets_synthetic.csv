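# SYNTHETIC stand-in calibration targets -- not transcribed from any published
# supplement or registry.  Landmark values were chosen once from general
# knowledge of population-based long-term outcome cohorts of elderly
# (age ~75) stroke patients and are meant to let the default pipeline run
# end-to-end; replace this file with study-specific targets for real analyses.
#
# Columns:
#   month            months since stroke onset
#   survival         cohort survival conditional on being alive at month 3
#   p02_among_alive  share of survivors who are functionally independent
#                    (mRS0-2); blank = no target at that landmark
month,survival,p02_among_alive
12,0.91,0.42
24,0.82,
36,0.74,0.46
48,0.67,
60,0.60,0.50
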