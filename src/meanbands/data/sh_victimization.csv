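condition,sex,cohort,n,fall_6,spring_6,fall_7,spring_7,fall_8,spring_8
SC,F,3,428,7.04,9.94,10.73,9.94,9.94,10.73
SC,M,3,401,8.89,9.94,10.73,8.89,9.94,9.94
DM,F,3,444,7.04,8.10,8.89,8.10,8.89,8.10
DM,M,3,399,8.89,9.94,10.73,8.10,9.94,8.89
SC,F,4,418,7.04,8.89,9.94,8.89,8.89,9.94
SC,M,4,392,8.89,9.94,10.73,8.89,8.89,9.94
DM,F,4,460,7.04,8.89,9.94,7.04,8.89,8.89
DM,M,4,359,8.89,8.89,10.73,8.89,8.89,8.89
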