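condition,sex,cohort,n,fall_6,spring_6,fall_7,spring_7,fall_8,spring_8
SC,F,3,428,-0.04,1.51,1.51,1.51,1.51,2.16
SC,M,3,401,-0.04,2.75,2.75,2.16,2.16,2.75
DM,F,3,444,-0.04,1.51,1.51,1.51,1.51,1.51
DM,M,3,399,-0.04,2.75,1.51,2.16,1.51,2.16
SC,F,4,418,-0.04,1.51,1.51,1.51,1.51,1.51
SC,M,4,392,-0.04,1.51,1.51,1.51,1.51,2.16
DM,F,4,460,-0.04,1.51,1.51,1.51,1.51,1.51
DM,M,4,359,-0.04,1.51,1.51,1.51,1.51,2.16
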