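outcome,chisq,df,rmsea,srmr
sv_perpetration,34.30,44,0.00,0.03
sv_victimization,44.82,46,0.00,0.03
sh_perpetration,55.86,44,0.03,0.04
sh_victimization,22.65,43,0.00,0.02
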