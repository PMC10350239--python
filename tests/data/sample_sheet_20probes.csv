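sample_id,subject_id,replicate,plate
S0000R1,subj0000,1,P1
S0000R2,subj0000,2,P2
S0001R1,subj0001,1,P1
S0001R2,subj0001,2,P2
S0002R1,subj0002,1,P1
S0002R2,subj0002,2,P2
S0003R1,subj0003,1,P1
S0003R2,subj0003,2,P2
S0004R1,subj0004,1,P1
S0004R2,subj0004,2,P2
S0005R1,subj0005,1,P1
S0005R2,subj0005,2,P2
S0006R1,subj0006,1,P1
S0006R2,subj0006,2,P2
S0007R1,subj0007,1,P1
S0007R2,subj0007,2,P2
S0008R1,subj0008,1,P1
S0008R2,subj0008,2,P2
S0009R1,subj0009,1,P1
S0009R2,subj0009,2,P2
S0010R1,subj0010,1,P1
S0010R2,subj0010,2,P2
S0011R1,subj0011,1,P1
S0011R2,subj0011,2,P2
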