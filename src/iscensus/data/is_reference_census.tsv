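element	family_class	n_orfs	recoding	fs_hairpin	length_bp	ir	dr	gc_pct	tpase_aa	n_full	full_range	n_partial	n_intact	intact_range
ISCaa1	IS1	1	none	1	759	17/21	0	35.7	232	1		6	1
ISCaa2	IS5	2	minus1	1	916	19/20	0	36.3	275	3	99-100	3	3	99-100
ISCaa3	IS5	2	minus1	0	914	22/23	0	36.5	275	10	99-100	5	9	99-100
ISCaa4	IS1	2	minus1	1	732	17/22	8/10	37.4	226	24	85-100	8	21	96-100
ISCaa5	IS982	1	none	1	932	18/21	0	38.2	274	10	99-100	24	8	99-100
ISCaa6	IS5	1	none	1	991	15/19	0	36.6	275	18	86-100	41	17	88-100
ISCaa7	IS110	1	none	1	1483	0	0	31.9	343	3	100	4	3	100
ISCaa8	IS5	2	plus1	1	893	18/22	0	39.5	264	6	99-100	6	6	99-100
ISCaa9	IS5	3	readthrough	1	881	18/21	0	38.8	253	15	100	3	15	100
ISCaa10	IS200/IS605	1	none	1	527	0	0	38.5	147	7	99-100	2	7	99-100
ISCaa11	IS481	1	none	1	1031	10/11	6/3	38.9	314	10	83-100	27	3	87-100
ISCaa12	IS481	1	none	1	1210	29/34	6/2	37.6	364	3	100	3	3	100
ISCaa13	IS5	2	plus1	1	860	17/21	0	40.7	253	2	99	7	1
ISCaa14	IS110	1	none	1	1256	0	0	38.1	326	2	97	0	1
ISCaa15	IS1182	1	none	1	1434	18/18	4/2	35.9	457	3	100	3	3	100
ISCaa16	IS6	1	none	1	837	15/18	0	37.4	235	5	82-100	1	5	85-100
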