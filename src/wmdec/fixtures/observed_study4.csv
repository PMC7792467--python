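span_type,list_type,length,prop
memory,2468,2,0.93
memory,2468,4,0.84
memory,2468,6,0.57
memory,2468,8,0.38
memory,2369,2,0.95
memory,2369,3,0.89
memory,2369,6,0.61
memory,2369,9,0.36
task,2468,2,0.90
task,2468,4,0.73
task,2468,6,0.51
task,2468,8,0.26
task,2369,2,0.92
task,2369,3,0.84
task,2369,6,0.57
task,2369,9,0.26
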