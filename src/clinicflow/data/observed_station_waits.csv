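station,mean,sd,n
registration,1.5,1.96,375
cash,0.7,1.02,375
novice_resident,60.67,49.89,375
experienced_resident,54.89,44.27,375
senior_staff,56.91,46.68,375
paraclinic,42.69,21.66,375
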