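# Default parameter catalog (version 1).
#
# Values listed here override the engines' built-in defaults; the file
# intentionally echoes the documented defaults so the effective study
# conditions are visible in one place.  Matrices and curve anchors live in
# code (see devcohort.engines.* and devcohort.trajectories); a custom
# catalog may override the dpn correlation matrix via
# `correlation_matrix` (19 lines of floats, PSD-checked at load).
version: 1
engines:
  dpn:
    z_bound: 4.0            # plausibility clamp on z-scores
    prevalence_male: 0.030  # autism threshold targets, by sex
    prevalence_female: 0.0075
  leer: {}
  osa:
    autism_prevalence_male: 0.025   # overall bound 2%, male > female
    autism_prevalence_female: 0.008
  paint:
    autism_prevalence: 0.03  # binomial assignment
    mcar_rate: 0.10          # brain-phenotype MCAR, variant 1
  site4802:
    autism_probability: 0.5  # "uniform probability", taken at face value
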