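primer,tbn,mbn,pbn,p_pct,ub,pic,emr,mi,rp,bsr_max,bsr_min
SCoT-1,7,3,4,57.14,1,0.22,3.02,0.67,7.33,835,175
SCoT-2,3,3,0,0,0,0,2.5,0,5,390,200
SCoT-6,3,2,1,33.33,0,0.11,1.7,0.18,3.67,530,300
SCoT-8,3,1,2,66.66,1,0.17,1.38,0.23,3.17,400,215
SCoT-9,11,4,7,63.63,1,0.21,6.05,1.25,14,1680,300
SCoT-11,7,3,4,57.14,0,0.25,3.43,0.86,8.33,1325,215
SCoT-12,4,2,2,50,1,0.09,2.35,0.21,5,500,210
SCoT-14,6,4,2,33.33,1,0.08,4.04,0.34,8.5,830,280
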