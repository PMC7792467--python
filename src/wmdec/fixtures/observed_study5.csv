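exp,list_kind,length,prop
1,single,3,0.96
1,single,4,0.96
1,single,5,0.89
1,single,6,0.79
1,alternating,3,0.82
1,alternating,4,0.88
1,alternating,5,0.83
1,alternating,6,0.74
2,few,3,0.86
2,few,4,0.83
2,few,5,0.79
2,few,6,0.71
2,many,3,0.85
2,many,4,0.79
2,many,5,0.70
2,many,6,0.68
3,few,3,0.94
3,few,4,0.91
3,few,5,0.84
3,few,6,0.71
3,few,7,0.70
3,few,8,0.60
3,many,3,0.90
3,many,4,0.90
3,many,5,0.81
3,many,6,0.67
3,many,7,0.72
3,many,8,0.49
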