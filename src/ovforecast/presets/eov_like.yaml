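# Endocrinology-like demand: strong Monday-to-Sunday decay, weekend trough,
# mild annual cycle, autocorrelated noise, a few holiday collapses.
weeks: 51
weekday_profile: [206, 193, 182, 171, 150, 86, 34]
trend_per_week: 0.0
annual_amplitude: 20.0
ar_coefficient: 0.5
noise_sd: 15.0
holidays:
  - [5, 1, 0.7]
  - [5, 2, 0.7]
  - [18, 4, 0.6]
  - [31, 3, 0.65]
seed: 20140106
label: eov_like
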