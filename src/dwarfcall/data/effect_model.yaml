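# Default height effect model for F2 simulation.
#
# Calibration constants, not inferences: the baseline is the tall-parent
# class mean and the per-locus / pairwise decrements are chosen so that the
# noise-free class means of an F2 population equal the published
# single-recessive (239.5 / 236.5 / 211.8 cm) and double-recessive
# (172.6 / 155.2 / 145.7 cm) group means.  residual_sd_cm is typical of the
# within-class standard deviations reported alongside those means.
baseline_cm: 265.0
single_effects:
  Dw1: 25.5
  Dw2: 28.5
  Dw3: 53.2
epistasis:
  Dw1Dw2: 38.4
  Dw1Dw3: 40.6
  Dw2Dw3: 28.1
residual_sd_cm: 22.0
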