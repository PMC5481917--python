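family	subgroup	A_thaliana	B_rapa	B_oleracea
UGT76	I	21	20	22
UGT82	I	1	2	2
UGT83	I	1	1	1
UGT74	II	7	11	14
UGT75	II	4	7	9
B_oleracea_specific	II	0	0	1
UGT84	II	6	9	10
UGT85	II	6	9	9
UGT86	II	2	3	3
UGT87	II	2	3	2
UGT71	III	14	19	20
B_rapa_specific	III	0	1	0
UGT72	III	9	14	13
UGT73	III	13	26	21
UGT78	III	4	1	1
UGT79	III	11	6	1
UGT80	III	2	2	4
UGT88	III	1	1	1
UGT89	III	4	4	5
UGT90	III	3	4	4
UGT91	III	3	3	3
UGT92	III	1	1	1
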