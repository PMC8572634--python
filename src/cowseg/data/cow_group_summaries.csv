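group,n,age_mean,age_sd,male_pct,Aco,A1,Pco,P1,entirety_incomplete,anterior_incomplete,posterior_incomplete
Yn,53,30,4,68,36,11,85,25,98,47,96
Sn,27,63,5,48,59,22,96,15,100,78,96
Male,40,42,15,100,30,10,93,18,100,40,98
Female,40,48,15,0,55,18,90,23,95,63,93
AMs,41,66,6,61,49,12,95,10,98,61,98
ASs,27,67,9,74,48,22,93,19,100,67,96
ESs,50,51,13,78,32,24,88,8,94,52,84
Ec,65,53,16,68,40,17,86,20,97,56,94
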