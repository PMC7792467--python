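task,burst,rt_ms,rt_sd,total_ms,total_sd,span,span_sd
parity,4,628,117,2467,400,5.16,0.78
parity,6,551,53,3251,316,4.58,1.23
parity,8,483,32,3724,218,3.69,0.63
location,4,484,61,1928,233,5.56,0.75
location,6,387,41,2297,239,5.52,0.62
location,8,361,39,2827,266,4.60,0.82
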