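condition,sex,cohort,n,fall_6,spring_6,fall_7,spring_7,fall_8,spring_8
SC,F,3,428,1.34,4.96,4.02,3.05,4.96,4.96
SC,M,3,401,1.34,4.96,4.96,4.02,4.96,4.96
DM,F,3,444,1.34,4.96,4.02,3.05,4.02,4.02
DM,M,3,399,1.34,4.96,4.96,4.02,4.02,4.02
SC,F,4,418,1.34,4.96,4.02,3.05,4.02,4.02
SC,M,4,392,1.34,4.96,4.96,3.05,4.96,4.96
DM,F,4,460,1.34,4.96,4.02,3.05,4.02,4.02
DM,M,4,359,1.34,4.96,4.96,3.05,4.96,4.96
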