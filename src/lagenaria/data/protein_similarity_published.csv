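,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
S1,1.000,,,,,,,,,
S2,0.882,1.000,,,,,,,,
S3,1.000,0.882,1.000,,,,,,,
S4,1.000,0.882,1.000,1.000,,,,,,
S5,1.000,0.882,1.000,1.000,1.000,,,,,
S6,0.941,0.824,0.941,0.941,0.941,1.000,,,,
S7,1.000,0.882,1.000,1.000,1.000,0.941,1.000,,,
S8,0.882,0.765,0.882,0.882,0.882,0.824,0.882,1.000,,
S9,0.941,0.938,0.941,0.941,0.941,0.882,0.941,0.824,1.000,
S10,1.000,0.882,1.000,1.000,1.000,0.941,1.000,0.882,0.941,1.000
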