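locus_id,assay,group,size_label,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
P01,protein,SDS-PAGE,126,1,1,1,1,1,1,1,0,1,1
P02,protein,SDS-PAGE,115,1,1,1,1,1,1,1,1,1,1
P03,protein,SDS-PAGE,100,1,1,1,1,1,1,1,0,1,1
P04,protein,SDS-PAGE,61,1,1,1,1,1,1,1,1,1,1
P05,protein,SDS-PAGE,46,1,1,1,1,1,1,1,1,1,1
P06,protein,SDS-PAGE,40,1,1,1,1,1,1,1,1,1,1
P07,protein,SDS-PAGE,35,1,1,1,1,1,1,1,1,1,1
P08,protein,SDS-PAGE,33,1,1,1,1,1,1,1,1,1,1
P09,protein,SDS-PAGE,26,1,1,1,1,1,1,1,1,1,1
P10,protein,SDS-PAGE,23,1,1,1,1,1,0,1,1,1,1
P11,protein,SDS-PAGE,20,1,1,1,1,1,1,1,1,1,1
P12,protein,SDS-PAGE,17,1,1,1,1,1,1,1,1,1,1
P13,protein,SDS-PAGE,15,1,1,1,1,1,1,1,1,1,1
P14,protein,SDS-PAGE,12,1,0,1,1,1,1,1,1,0,1
P15,protein,SDS-PAGE,11,1,0,1,1,1,1,1,1,1,1
P16,protein,SDS-PAGE,10,1,1,1,1,1,1,1,1,1,1
P17,protein,SDS-PAGE,9,1,1,1,1,1,1,1,1,1,1
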