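bait_id	t_screen1	t_screen2	t_overlap_num	t_overlap_den	t_known_num	t_known_den	m_screen1	m_screen2	m_overlap_num	m_overlap_den	m_known_num	m_known_den	consensus_num	consensus_den
Rhs7-2_element	10	13	6	10	0	2	7	7	7	7	0	2	3	10
Mlcrhs4_element	9	15	9	9	0	1	3	3	3	3	0	1	3	9
Ptgs2_promoter	6	6	1	6	1	9	2	2	1	2	1	9	1	1
Pou5f1_promoter	6	11	3	6	3	7	9	9	8	9	4	7	3	8
Mcts2-Id1_enhancer	6	9	3	6	-	-	2	3	2	2	-	-	2	3
Fos_promoter	14	11	3	14	0	4	3	3	2	3	0	4	0	5
Mmp9_promoter	5	7	3	5	1	5	2	2	2	2	2	5	1	4
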