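abbreviation,name,cas,odor_threshold_mg_m3
B,Benzene,71-43-2,2.53
T,Toluene,108-88-3,1.43
E,Ethylbenzene,100-41-4,0.45
P,n-Propylbenzene,103-65-7,0.57
O,o-Xylene,95-47-6,1.37
M,m-Xylene,108-38-3,1.55
S,Styrene,100-42-5,0.19
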