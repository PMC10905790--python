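# One axisymmetric tuber expanding to 20 mm radius over four days,
# 17-21 degC chamber cycle.
preset: radish
seed: 3
max_radius_mm: 20.0
noise_sigma_ue: 1.0
duration_h: 96.0
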