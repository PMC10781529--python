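locus_id,assay,group,size_label,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
PPO1,isozyme,PPO,0.3,2,3,3,2,3,2,2,3,2,2
PPO2,isozyme,PPO,0.6,2,3,0,0,0,0,0,0,0,0
PPO3,isozyme,PPO,0.65,1,2,3,3,2,2,1,3,3,1
PPO4,isozyme,PPO,0.7,1,2,3,2,1,2,2,2,1,1
PPO5,isozyme,PPO,0.75,3,3,3,3,3,3,3,3,1,1
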