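column,weighted_mean
base_case,55.36
scenario_1,47.86
scenario_2,49.83
scenario_3,33.26
scenario_4,50.26
scenario_5,40.87
scenario_6,44.79
scenario_7,23.02
scenario_8,34.10
scenario_9,15.83
scenario_10,18.48
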