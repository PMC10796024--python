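,A2,A5,A16,A19,A20,A26,A27,A29,A39,A41,A45,A48,A58
P1,0,0,0,0,0,0,0,0,0,0,0,0,0
P2,0,0,0,0,0,0,0,0,0,0,0,1,0
P3,0,0,0,0,0,0,0,0,0,0,0,0,0
P4,0,0,0,0,0,0,0,0,0,0,0,1,0
P5,0,0,0,0,0,0,0,0,0,0,0,1,0
P6,0,0,0,0,0,0,0,0,0,0,0,1,0
P7,0,0,0,0,0,0,0,0,0,0,0,0,0
P8,0,0,0,0,0,0,0,0,0,0,0,0,0
P9,1,1,1,0,0,1,1,0,0,0,1,1,0
P10,0,0,0,0,0,0,0,0,0,0,0,0,0
P11,1,0,0,0,0,0,1,0,0,0,1,0,0
P12,0,0,0,0,0,0,0,0,0,0,0,1,0
P13,0,0,0,0,0,0,0,0,0,0,0,0,0
P14,0,0,0,0,0,0,0,0,0,0,0,1,0
P15,1,0,0,0,0,0,0,0,0,0,0,1,0
P16,0,1,0,0,1,0,1,1,0,0,1,1,0
P17,0,0,0,0,0,0,0,0,0,0,0,0,0
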