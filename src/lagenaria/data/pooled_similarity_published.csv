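,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
S1,1.000,,,,,,,,,
S2,0.926,1.000,,,,,,,,
S3,0.926,0.852,1.000,,,,,,,
S4,0.926,0.852,1.000,1.000,,,,,,
S5,0.926,0.852,1.000,1.000,1.000,,,,,
S6,0.889,0.815,0.960,0.960,0.960,1.000,,,,
S7,0.926,0.825,1.000,1.000,1.000,0.960,1.000,,,
S8,0.852,0.778,0.920,0.920,0.920,0.880,0.920,1.000,,
S9,0.889,0.885,0.960,0.960,0.960,0.920,0.960,0.880,1.000,
S10,0.926,0.852,1.000,1.000,1.000,0.960,1.000,0.920,0.960,1.000
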