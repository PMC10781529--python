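,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
S1,1.000,,,,,,,,,
S2,0.789,1.000,,,,,,,,
S3,0.771,0.778,1.000,,,,,,,
S4,0.737,0.700,0.722,1.000,,,,,,
S5,0.763,0.725,0.703,0.861,1.000,,,,,
S6,0.800,0.757,0.788,0.853,0.829,1.000,,,,
S7,0.811,0.816,0.703,0.811,0.889,0.829,1.000,,,
S8,0.757,0.763,0.743,0.757,0.737,0.771,0.833,1.000,,
S9,0.784,0.744,0.771,0.737,0.675,0.703,0.763,0.857,1.000,
S10,0.842,0.800,0.737,0.842,0.868,0.811,0.868,0.816,0.795,1.000
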