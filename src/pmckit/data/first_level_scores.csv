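policy_id,X1,X2,X3,X4,X5,X6,X7,X8,X9
P11,0.67,1.00,1.00,0.67,1.00,0.67,1.00,1.00,1.00
P6,1.00,1.00,1.00,1.00,1.00,1.00,0.67,0.67,0.67
P2,1.00,1.00,1.00,0.33,1.00,1.00,0.67,0.67,0.67
P4,1.00,1.00,1.00,0.33,1.00,1.00,0.67,0.67,0.67
P9,1.00,1.00,1.00,0.33,0.67,1.00,1.00,0.67,0.67
P12,1.00,0.67,1.00,0.67,0.67,0.33,1.00,0.67,1.00
P13,1.00,0.67,1.00,0.67,0.67,0.33,1.00,0.67,1.00
P18,1.00,0.67,1.00,0.67,0.67,0.33,1.00,0.67,1.00
P5,0.67,0.67,1.00,0.33,1.00,1.00,1.00,0.00,1.00
P8,0.67,0.67,1.00,0.67,0.67,0.67,1.00,0.33,1.00
P1,1.00,0.67,0.67,0.67,0.67,0.67,0.67,0.67,0.67
P14,0.67,1.00,0.67,0.67,1.00,0.00,1.00,0.67,0.67
P7,0.67,0.67,1.00,0.33,0.67,1.00,1.00,0.00,1.00
P20,1.00,0.33,1.00,0.67,0.67,0.33,0.67,0.67,1.00
P21,0.67,1.00,0.67,0.67,0.67,0.00,1.00,0.67,1.00
P19,0.67,0.67,1.00,0.67,0.33,0.33,0.67,0.67,1.00
P10,0.67,0.67,1.00,0.67,0.33,0.33,0.67,0.33,1.00
P15,0.67,0.67,0.33,0.33,0.33,0.00,1.00,0.67,1.00
P3,0.67,0.67,0.33,0.33,0.33,0.00,1.00,0.67,0.67
P16,0.33,0.67,0.33,0.33,0.33,0.00,0.67,0.67,1.00
P17,0.33,0.67,0.33,0.33,0.33,0.00,0.67,0.67,1.00
P22,0.33,0.67,0.33,0.33,0.33,0.00,0.67,0.67,1.00
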