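cti,task_trans,dim_trans,rt_ms
0,rep,rep,1752
0,rep,sw,2020
0,sw,rep,2042
0,sw,sw,2005
300,rep,rep,1485
300,rep,sw,1739
300,sw,rep,1728
300,sw,sw,1673
1000,rep,rep,1073
1000,rep,sw,1326
1000,sw,rep,1320
1000,sw,sw,1294
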