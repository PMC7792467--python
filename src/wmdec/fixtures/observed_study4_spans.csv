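list_type,span_type,span
2468,memory,6.58
2468,task,6.14
2369,memory,7.25
2369,task,6.64
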