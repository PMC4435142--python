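sample_id,mixture,component,ln_oav,measured_oi
S01,T+E,T,3.36,5.4
S01,T+E,E,3.54,5.4
S02,T+E,T,3.03,4.0
S02,T+E,E,2.44,4.0
S03,T+E,T,2.67,3.3
S03,T+E,E,2.44,3.3
S04,T+S,T,1.65,2.7
S04,T+S,S,2.04,2.7
S05,T+S,T,3.36,4.5
S05,T+S,S,2.04,4.5
S06,T+S,T,2.34,6.2
S06,T+S,S,4.53,6.2
S07,T+E+M,T,2.34,3.8
S07,T+E+M,E,3.54,3.8
S07,T+E+M,M,2.80,3.8
S08,T+E+M,T,2.34,5.0
S08,T+E+M,E,2.44,5.0
S08,T+E+M,M,3.49,5.0
S09,T+E+M,T,1.65,3.5
S09,T+E+M,E,1.78,3.5
S09,T+E+M,M,2.15,3.5
S10,E+P+S,E,3.54,5.4
S10,E+P+S,P,2.20,5.4
S10,E+P+S,S,3.83,5.4
S11,E+P+S,E,4.24,6.8
S11,E+P+S,P,2.20,6.8
S11,E+P+S,S,4.53,6.8
S12,E+P+S,E,2.82,4.5
S12,E+P+S,P,2.20,4.5
S12,E+P+S,S,2.65,4.5
S13,T+E+M+S,T,4.24,4.8
S13,T+E+M+S,E,2.20,4.8
S13,T+E+M+S,M,3.83,4.8
S13,T+E+M+S,S,2.15,4.8
S14,T+E+M+S,T,2.20,4.5
S14,T+E+M+S,E,3.15,4.5
S14,T+E+M+S,M,2.20,4.5
S14,T+E+M+S,S,2.15,4.5
S15,T+E+M+S,T,1.85,3.5
S15,T+E+M+S,E,1.77,3.5
S15,T+E+M+S,M,2.20,3.5
S15,T+E+M+S,S,2.15,3.5
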