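genotype,polarity,group,size_label
S1,negative,SCoT-14,830
S2,positive,SCoT-9,460
S2,positive,SCoT-12,415
S3,negative,SCoT-12,500
S8,positive,SCoT-1,835
S9,positive,SCoT-8,400
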