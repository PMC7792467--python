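transition,cti,rt_ms
repeat,0,1132
repeat,100,976
repeat,200,929
repeat,300,850
repeat,400,820
repeat,500,790
repeat,600,760
repeat,700,764
repeat,800,769
repeat,900,750
switch,0,1463
switch,100,1330
switch,200,1237
switch,300,1127
switch,400,1063
switch,500,1013
switch,600,995
switch,700,964
switch,800,918
switch,900,917
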