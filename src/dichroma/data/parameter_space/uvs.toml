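# Swept parameter space for the UVS eye type.
# Average values are the established reference parameterization;
# entries flagged `placeholder = true` are stand-ins for literature
# extremes that must be filled in from measured physiology before
# quantitative use (sweeps refuse them unless explicitly allowed).

eye_type = "UVS"
reference_weber = 0.05
illuminants = ["ideal", "forest_shade", "woodland_shade", "blue_sky", "D65", "woodland_gaps", "cloudy_sky"]
t50_values = [314.0, 324.0, 334.0, 344.0]
expected_sizes = [7, 4, 11, 9, 9]

[[sensitivity_sets]]
label = "average"
lambda_max = [367.0, 444.0, 501.0, 564.0]
placeholder = false

[[sensitivity_sets]]
label = "SWS1_min"
lambda_max = [355.0, 444.0, 501.0, 564.0]
placeholder = true

[[sensitivity_sets]]
label = "SWS1_max"
lambda_max = [379.0, 444.0, 501.0, 564.0]
placeholder = true

[[sensitivity_sets]]
label = "SWS2_min"
lambda_max = [367.0, 432.0, 501.0, 564.0]
placeholder = true

[[sensitivity_sets]]
label = "SWS2_max"
lambda_max = [367.0, 456.0, 501.0, 564.0]
placeholder = true

[[sensitivity_sets]]
label = "MWS_min"
lambda_max = [367.0, 444.0, 489.0, 564.0]
placeholder = true

[[sensitivity_sets]]
label = "MWS_max"
lambda_max = [367.0, 444.0, 513.0, 564.0]
placeholder = true

[[sensitivity_sets]]
label = "LWS_min"
lambda_max = [367.0, 444.0, 501.0, 552.0]
placeholder = true

[[sensitivity_sets]]
label = "LWS_max"
lambda_max = [367.0, 444.0, 501.0, 576.0]
placeholder = true

[[sensitivity_sets]]
label = "all_min"
lambda_max = [355.0, 432.0, 489.0, 552.0]
placeholder = true

[[sensitivity_sets]]
label = "all_max"
lambda_max = [379.0, 456.0, 513.0, 576.0]
placeholder = true

[[droplet_sets]]
label = "average"
cut_bmid = [[411.0, 0.0278], [511.0, 0.023], [572.0, 0.022]]
placeholder = false

[[droplet_sets]]
label = "C_min"
cut_bmid = [[396.0, 0.0278], [511.0, 0.023], [572.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "C_max"
cut_bmid = [[426.0, 0.0278], [511.0, 0.023], [572.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "Y_min"
cut_bmid = [[411.0, 0.0278], [496.0, 0.023], [572.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "Y_max"
cut_bmid = [[411.0, 0.0278], [526.0, 0.023], [572.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "R_min"
cut_bmid = [[411.0, 0.0278], [511.0, 0.023], [557.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "R_max"
cut_bmid = [[411.0, 0.0278], [511.0, 0.023], [587.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "all_min"
cut_bmid = [[396.0, 0.0278], [496.0, 0.023], [557.0, 0.022]]
placeholder = true

[[droplet_sets]]
label = "all_max"
cut_bmid = [[426.0, 0.0278], [526.0, 0.023], [587.0, 0.022]]
placeholder = true

[[density_ratios]]
label = "pekin_robin_1224"
densities = [1.0, 2.0, 2.0, 4.0]
placeholder = false

[[density_ratios]]
label = "anous_minutus"
densities = [1.0, 9.59, 16.82, 14.29]
placeholder = false

[[density_ratios]]
label = "puffinus_pacificus"
densities = [1.0, 0.68, 1.04, 1.44]
placeholder = false

[[density_ratios]]
label = "placeholder_ratio_1"
densities = [1.0, 1.0, 1.0, 1.0]
placeholder = true

[[density_ratios]]
label = "placeholder_ratio_2"
densities = [1.0, 1.5, 2.5, 3.0]
placeholder = true

[[density_ratios]]
label = "placeholder_ratio_3"
densities = [1.0, 2.6, 3.0, 3.2]
placeholder = true

[[density_ratios]]
label = "placeholder_ratio_4"
densities = [1.0, 1.2, 2.0, 5.0]
placeholder = true

[[density_ratios]]
label = "placeholder_ratio_5"
densities = [0.5, 2.0, 2.0, 4.0]
placeholder = true

[[density_ratios]]
label = "placeholder_ratio_6"
densities = [2.0, 2.0, 2.0, 4.0]
placeholder = true
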