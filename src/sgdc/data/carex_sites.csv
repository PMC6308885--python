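population,name,n,richness,he_ds1,he_ds2,he_ds3,he_ds4,he_ds5,he_aflp,discordant
S1,Cop4,4,11,0.072,0.071,0.073,0.080,0.043,0.070,0
S5,Cop5,10,14,0.084,0.082,0.084,0.097,0.088,0.068,0
S6,Cop6,9,19,0.088,0.090,0.089,0.072,0.019,0.131,1
S7,Hua3,10,16,0.134,0.143,0.136,0.080,0.041,0.095,0
S8,Hua2,9,17,0.127,0.136,0.129,0.069,0.052,0.075,0
S9,Hua1,10,16,0.122,0.129,0.124,0.076,0.018,0.082,0
S10,Elq3,10,15,0.114,0.120,0.117,0.077,0.015,0.091,0
S11,Elq4,10,10,0.159,0.163,0.161,0.136,0.082,0.113,0
S12,Elq2,10,11,0.130,0.124,0.129,0.165,0.175,0.089,0
S14,Lim3,9,19,0.145,0.152,0.148,0.097,0.018,0.105,0
S15,Lim4,10,19,0.143,0.152,0.146,0.081,0.028,0.097,0
S16,Lim1,9,15,0.099,0.108,0.101,0.042,0.014,0.077,0
S17,Lim2,9,19,0.134,0.144,0.136,0.068,0.046,0.111,0
S18,Cho3,10,21,0.197,0.205,0.201,0.143,0.042,0.170,0
S19,Cho2,9,20,0.219,0.227,0.224,0.169,0.018,0.254,0
S20,Cho1,10,17,0.175,0.180,0.177,0.140,0.055,0.187,0
S21,Cho4,10,19,0.062,0.060,0.062,0.076,0.102,0.137,1
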