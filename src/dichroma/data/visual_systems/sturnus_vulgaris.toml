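# Visual-system parameter file: sturnus vulgaris.
# PLACEHOLDER values: replace with measured physiology before use.
eye_type = "UVS"
t50 = 324.0
lambda_max = [362, 449, 504, 563]
densities = [1.0, 2.0, 2.0, 4.0]
reference_weber = 0.05
placeholder = true
[[droplets]]
kind = "T"
[[droplets]]
kind = "C"
lambda_cut = 411
b_mid = 0.0278
[[droplets]]
kind = "Y"
lambda_cut = 511
b_mid = 0.023
[[droplets]]
kind = "R"
lambda_cut = 572
b_mid = 0.022
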