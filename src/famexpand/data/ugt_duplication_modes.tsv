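family	At_total	At_wgt	At_td	Bra_total	Bra_wgt	Bra_td	Bol_total	Bol_wgt	Bol_td
UGT71	14	9	13	20	12	11	20	12	8
UGT72	9	4	2	14	7	4	13	6	2
UGT73	13	8	13	26	14	19	21	12	11
UGT74	7	6	2	11	10	4	14	7	5
UGT75	4	4	0	7	3	2	10	5	4
UGT76	21	15	15	20	15	11	22	16	9
UGT78	4	1	3	1	1	0	1	1	0
UGT79	11	2	4	6	1	4	1	1	0
UGT80	2	2	0	2	2	0	4	4	0
UGT82	1	1	0	2	2	0	2	2	0
UGT83	1	0	0	1	0	0	1	0	0
UGT84	6	6	5	9	8	4	10	8	3
UGT85	6	6	4	9	7	6	9	4	3
UGT86	2	2	0	3	2	0	3	2	0
UGT87	2	0	2	3	0	2	2	0	0
UGT88	1	1	0	1	1	0	1	1	0
UGT89	4	2	0	4	3	0	5	3	4
UGT90	3	3	0	4	4	0	4	4	0
UGT91	3	1	0	3	1	0	3	1	0
UGT92	1	1	0	1	1	0	1	1	0
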