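# Core declarative vocabulary shared by every simulated task family.
# Structural class nodes
CUE
GOAL
TSKSET
MEMTSK
TARGET
MEMITEM
MEMCUE
RCLCUE
RESPONSE
DIMCLS
MAGCAT
PARCAT
FRMCAT
LOCCAT
DIGIT
NUMWORD
LETTER
COORDC
# Categories (opposed pairs inhibit each other laterally)
SMALL syllables=1 link=SUP:MAGCAT link=OPP:LARGE
LARGE syllables=1 link=SUP:MAGCAT
ODD syllables=1 link=SUP:PARCAT link=OPP:EVEN
EVEN syllables=2 link=SUP:PARCAT
DIG syllables=2 link=SUP:FRMCAT link=OPP:WRD
WRD syllables=1 link=SUP:FRMCAT
ABOVE syllables=2 link=SUP:LOCCAT link=OPP:BELOW
BELOW syllables=2 link=SUP:LOCCAT
DIGDIM link=SUP:DIMCLS link=OPP:NUMDIM
NUMDIM link=SUP:DIMCLS
# Responses
LEFT syllables=1 link=SUP:RESPONSE link=OPP:RIGHT
RIGHT syllables=1 link=SUP:RESPONSE
# Fixation and memory-task control symbols
CROSS
DUAL link=SUP:COORDC
CMEM syllables=1 link=SUP:CUE link=SUP:MEMCUE link=PROP:MEM link=OPP:CRCL
CRCL syllables=1 link=SUP:CUE link=SUP:RCLCUE
MEM syllables=1 link=SUP:GOAL link=PROP:MEMTS
MEMTS link=SUP:MEMTSK
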