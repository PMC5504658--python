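# Noise-free constant control: every model should forecast it exactly.
weeks: 51
weekday_profile: [100, 100, 100, 100, 100, 100, 100]
trend_per_week: 0.0
annual_amplitude: 0.0
ar_coefficient: 0.0
noise_sd: 0.0
holidays: []
seed: 1
label: flat_control
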