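server,component,base_case,scenario_1,scenario_2,scenario_3,scenario_4,scenario_5,scenario_6,scenario_7,scenario_8,scenario_9,scenario_10
novice_resident,before_attendance,32.42,32.46,32.41,12.15,32.40,22.27,32.35,12.17,22.42,12.04,12.10
novice_resident,after_attendance,27.18,18.48,9.22,6.97,27.02,15.66,8.68,7.06,5.06,1.43,1.96
novice_resident,total,59.60,50.94,41.63,19.12,59.42,37.93,41.03,19.23,27.48,13.47,14.06
experienced_resident,before_attendance,32.42,32.46,32.41,12.15,32.40,22.27,32.35,12.17,22.42,12.04,12.10
experienced_resident,after_attendance,21.61,5.21,18.45,9.37,22.41,15.25,5.075,10.93,3.77,2.46,2.49
experienced_resident,total,54.03,37.67,50.86,21.52,54.81,37.52,37.43,23.10,26.19,14.50,14.59
senior_staff,before_attendance,24.39,28.32,30.30,51.80,13.09,25.75,32.78,15.52,32.36,19.68,17.61
senior_staff,after_attendance,25.13,33.74,33.87,33.30,9.76,27.70,34.24,14.93,30.80,3.53,17.50
senior_staff,total,49.52,62.06,64.17,85.03,22.87,53.45,67.02,30.45,63.16,23.21,35.11
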