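sample_id,n_components,oi_measured,oi_mvm_reported,oi_scm_reported
S01,2,5.4,4.9,3.8
S02,2,4.0,3.9,3.2
S03,2,3.3,3.6,2.9
S04,2,2.7,2.6,2.2
S05,2,4.5,4.0,3.6
S06,2,6.2,5.2,4.8
S07,3,3.8,4.7,3.8
S08,3,5.0,4.5,3.7
S09,3,3.5,3.0,2.3
S10,3,5.4,5.3,4.1
S11,3,6.8,6.2,4.8
S12,3,4.5,4.1,3.0
S13,4,4.8,5.5,4.5
S14,4,4.5,4.1,3.4
S15,4,3.5,3.3,2.4
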