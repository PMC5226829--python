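# Visual-system parameter file: pavo cristatus.
# PLACEHOLDER values: replace with measured physiology before use.
eye_type = "VS"
t50 = 348.0
lambda_max = [432, 477, 537, 605]
densities = [1.0, 2.0, 2.0, 4.0]
reference_weber = 0.05
placeholder = true
[[droplets]]
kind = "T"
[[droplets]]
kind = "C"
lambda_cut = 447
b_mid = 0.0294
[[droplets]]
kind = "Y"
lambda_cut = 510
b_mid = 0.028
[[droplets]]
kind = "R"
lambda_cut = 570
b_mid = 0.02
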