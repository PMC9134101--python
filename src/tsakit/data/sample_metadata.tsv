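sample_id	sample_type	msi_status
COLO205	cell_line	MSS
HCT116	cell_line	MSI
RKO	cell_line	MSI
SW620	cell_line	MSS
S1	tissue	MSS
S2	tissue	MSS
S3	tissue	MSS
S4	tissue	MSS
S5	tissue	MSI
S6	tissue	MSI
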