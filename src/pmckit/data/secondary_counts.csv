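code,count,n,imputed
X1-1,21,22,0
X1-2,19,22,0
X1-3,10,22,0
X2-1,21,22,0
X2-2,22,22,0
X2-3,7,22,0
X3-1,16,22,0
X3-2,22,22,0
X3-3,15,22,0
X4-1,14,22,0
X4-2,8,22,0
X4-3,13,22,0
X5-1,21,22,0
X5-2,8,22,0
X5-3,14,22,0
X6-1,8,22,0
X6-2,8,22,0
X6-3,14,22,0
X7-1,16,22,0
X7-2,22,22,0
X7-3,18,22,0
X8-1,20,22,1
X8-2,18,22,1
X8-3,1,22,0
X9-1,15,22,0
X9-2,22,22,0
X9-3,22,22,0
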