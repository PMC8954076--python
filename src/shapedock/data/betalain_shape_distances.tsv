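# Published global and per-element Riemannian shape distances (radians,
# 3-decimal display) between each parent compound and its deprotonated
# anions, with the matching proton affinity (kcal/mol).
label	compound	site	PA	rd	rd_O	rd_C	rd_H
BnAC15	Bn	C15	14.2	0.013	0.021	0.005	0.006
BnAC17	Bn	C17	11.6	0.010	0.015	0.006	0.009
BnAC2	Bn	C2	15.0	0.011	0.014	0.007	0.009
BnAC6	Bn	C6	26.2	0.013	0.011	0.011	0.014
BnAN16	Bn	N16	23.3	0.036	0.059	0.014	0.022
IsoBnAC15	IsoBn	C15	15.2	0.011	0.012	0.007	0.010
IsoBnAC17	IsoBn	C17	11.4	0.008	0.008	0.008	0.008
IsoBnAC2	IsoBn	C2	15.0	0.011	0.012	0.010	0.012
IsoBnAC6	IsoBn	C6	26.2	0.011	0.010	0.008	0.013
IsoBnAN16	IsoBn	N16	23.7	0.021	0.031	0.014	0.012
BdAC15	Bd	C15	14.2	0.013	0.021	0.004	0.006
BdAC17	Bd	C17	11.6	0.008	0.008	0.007	0.009
BdAC2	Bd	C2	14.9	0.009	0.008	0.008	0.008
BdAC5	Bd	C5	25.8	0.021	0.018	0.016	0.023
BdAC6	Bd	C6	22.9	0.013	0.010	0.010	0.014
BdAN16	Bd	N16	23.2	0.034	0.054	0.013	0.022
IsoBdAC15	IsoBd	C15	12.9	0.012	0.013	0.009	0.012
IsoBdAC17	IsoBd	C17	10.8	0.007	0.005	0.008	0.007
IsoBdAC2	IsoBd	C2	14.3	0.013	0.023	0.005	0.005
IsoBdAC5	IsoBd	C5	17.6	0.070	0.035	0.013	0.098
IsoBdAC6	IsoBd	C6	26.7	0.070	0.031	0.010	0.099
IsoBdAN16	IsoBd	N16	20.8	0.061	0.099	0.015	0.046
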