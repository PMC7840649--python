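condition,sex,cohort,n,fall_6,spring_6,fall_7,spring_7,fall_8,spring_8
SC,F,3,428,2.48,2.48,2.48,2.48,2.48,3.37
SC,M,3,401,3.37,3.37,3.37,3.37,3.37,3.37
DM,F,3,444,2.48,2.48,2.48,2.48,2.48,2.48
DM,M,3,399,3.37,3.37,3.37,3.37,3.37,3.37
SC,F,4,418,2.48,2.48,2.48,2.48,2.48,3.37
SC,M,4,392,2.48,2.48,2.48,2.48,2.48,2.48
DM,F,4,460,2.48,2.48,2.48,2.48,2.48,2.48
DM,M,4,359,2.48,2.48,2.48,2.48,2.48,2.48
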