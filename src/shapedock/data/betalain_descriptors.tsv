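# Published aqueous-phase descriptor values (kcal/mol) for betanin (Bn),
# betanidin (Bd) and their C15-epimers (IsoBn, IsoBd), one row per
# deprotonation site.  IP is compound-level and repeated on every row.
compound	site	BDE	PA	ETE	IP	PDE
Bn	C2	84.8	15.0	69.9	74.1	10.7
Bn	C15	84.1	14.2	69.9	74.1	10.0
Bn	C17	79.6	11.6	68.1	74.1	5.5
Bn	N16	83.7	23.3	60.4	74.1	9.6
Bn	C6	75.4	26.2	49.2	74.1	1.3
IsoBn	C2	85.0	15.0	70.0	74.2	10.8
IsoBn	C15	84.6	15.2	69.4	74.2	10.4
IsoBn	C17	79.6	11.4	68.2	74.2	5.4
IsoBn	N16	84.0	23.7	60.2	74.2	9.8
IsoBn	C6	75.4	26.2	49.2	74.2	1.2
Bd	C2	85.3	14.9	70.4	75.0	10.3
Bd	C15	84.8	14.2	70.6	75.0	5.2
Bd	C17	80.2	11.6	68.6	75.0	9.8
Bd	N16	83.8	23.2	60.6	75.0	8.8
Bd	C6	73.3	22.9	50.4	75.0	-1.7
Bd	C5	75.4	25.8	49.6	75.0	0.4
IsoBd	C2	85.1	14.3	70.8	74.8	10.3
IsoBd	C15	83.9	12.9	71.0	74.8	9.0
IsoBd	C17	80.0	10.8	69.2	74.8	5.2
IsoBd	N16	81.7	20.8	60.9	74.8	6.9
IsoBd	C6	77.5	26.7	50.7	74.8	2.7
IsoBd	C5	70.6	17.6	53.0	74.8	-4.3
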