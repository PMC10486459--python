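patient_id,survival_months,event,group
S01,6,1,A
S02,7,0,A
S03,10,1,A
S04,15,1,A
S05,19,0,A
S06,25,1,A
S07,5,1,B
S08,8,1,B
S09,12,1,B
S10,14,1,B
S11,20,1,B
S12,30,0,B
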