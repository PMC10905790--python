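# Three crown roots inside the inner spiral layer, 12-day recording,
# 25-30 degC chamber cycle, 1 microstrain reflectometer noise.
preset: rice
n_tips: 3
seed: 5
noise_sigma_ue: 1.0
duration_h: 288.0
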