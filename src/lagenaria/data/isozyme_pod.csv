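locus_id,assay,group,size_label,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
POD1,isozyme,POD,0.3,2,2,2,2,2,1,1,3,2,2
POD2,isozyme,POD,0.6,3,2,0,0,0,0,0,0,0,0
POD3,isozyme,POD,0.65,3,2,3,3,2,2,2,2,3,2
POD4,isozyme,POD,0.7,2,2,2,3,2,1,1,1,2,1
POD5,isozyme,POD,0.75,3,2,2,3,2,1,3,1,2,2
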