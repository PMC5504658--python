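# Respiratory-like demand: flat workdays, near-empty weekends, mild annual
# cycle, autocorrelated noise, holiday collapses.
weeks: 51
weekday_profile: [173, 178, 145, 161, 163, 18, 11]
trend_per_week: 0.0
annual_amplitude: 15.0
ar_coefficient: 0.5
noise_sd: 12.0
holidays:
  - [5, 1, 0.7]
  - [18, 4, 0.6]
  - [31, 3, 0.65]
seed: 20140107
label: rov_like
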