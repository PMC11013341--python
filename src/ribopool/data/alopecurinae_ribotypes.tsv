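species	sample_id	origin	total_reads	label	count	percent
Alopecurus aequalis	M36	Russia: Altai Krai, Mamontovsky District	2173	Ae1	473	22
Alopecurus aequalis	M36	Russia: Altai Krai, Mamontovsky District	2173	Ae2	169	8
Alopecurus aequalis	M36	Russia: Altai Krai, Mamontovsky District	2173	Ae3	161	7
Alopecurus aequalis	M36	Russia: Altai Krai, Mamontovsky District	2173	Ae4	140	6
Alopecurus alpinus	L22	Canada: Franklin district, Banks Island	10709	Al1	3709	35
Alopecurus alpinus	L22	Canada: Franklin district, Banks Island	10709	Al2	2396	22
Alopecurus arundinaceus	22	Russia: Khakassia Republic	16316	Ar1	2864	18
Alopecurus arundinaceus	22	Russia: Khakassia Republic	16316	Ar2	2504	15
Alopecurus brachystachyus	M13	Russia: Zabaykalsky Krai	7373	Br	3485	47
Alopecurus x brachystylus	21	Russia: Novgorod Oblast	26133	Ae1	5828	22
Alopecurus x brachystylus	21	Russia: Novgorod Oblast	26133	Ae3	2331	9
Alopecurus x brachystylus	21	Russia: Novgorod Oblast	26133	Pr5	2095	8
Alopecurus x brachystylus	21	Russia: Novgorod Oblast	26133	B	1722	7
Alopecurus x brachystylus	21	Russia: Novgorod Oblast	26133	PR1	1087	4
Alopecurus brevifolius	L21	Russia: Karachay-Cherkessia, Teberda	20957	Bf1	7380	35
Alopecurus brevifolius	L21	Russia: Karachay-Cherkessia, Teberda	20957	Bf2	1879	9
Alopecurus brevifolius	L21	Russia: Karachay-Cherkessia, Teberda	20957	Bf3	1643	8
Alopecurus brevifolius	L21	Russia: Karachay-Cherkessia, Teberda	20957	Bf4	1124	5
Alopecurus geniculatus	L18	Ukraine: Lviv Oblast	5263	Ae1	1809	34
Alopecurus geniculatus	L18	Ukraine: Lviv Oblast	5263	G	1072	20
Alopecurus magellanicus	L14	South Georgia	5142	Am1	2051	40
Alopecurus magellanicus	L14	South Georgia	5142	Am2	447	9
Alopecurus magellanicus	L14	South Georgia	5142	Am3	235	5
Alopecurus x marssonii	M11	Finland	1880	Ae1	465	22
Alopecurus x marssonii	M11	Finland	1880	Ae2	164	8
Alopecurus x marssonii	M11	Finland	1880	Ae3	158	7
Alopecurus x marssonii	M11	Finland	1880	Ae4	133	6
Alopecurus myosuroides	20	Russia: Dagestan Republic	18721	My1	10044	56
Alopecurus myosuroides var. breviaristatus	L16	Russia: Krasnodar Krai	12275	My1	3292	27
Alopecurus myosuroides var. breviaristatus	L16	Russia: Krasnodar Krai	12275	My2-2	1971	12
Alopecurus myosuroides var. breviaristatus	L16	Russia: Krasnodar Krai	12275	My2-3	1478	9
Alopecurus ponticus	L20	Russia: Karachay-Cherkessia, Teberda	9229	Po1	2234	24
Alopecurus ponticus	L20	Russia: Karachay-Cherkessia, Teberda	9229	Po2	1691	18
Alopecurus ponticus	L20	Russia: Karachay-Cherkessia, Teberda	9229	Po3	1319	14
Alopecurus ponticus	M8	Russia: Karachay-Cherkessia, Teberda	13553	Po1	3562	26
Alopecurus ponticus	M8	Russia: Karachay-Cherkessia, Teberda	13553	Po2	3143	23
Alopecurus ponticus	M8	Russia: Karachay-Cherkessia, Teberda	13553	Po3	1406	10
Alopecurus ponticus	M8	Russia: Karachay-Cherkessia, Teberda	13553	Po4	1142	8
Alopecurus pratensis	23	Russia: Altai Krai	26172	Pr1	5561	21
Alopecurus pratensis	23	Russia: Altai Krai	26172	Pr2	2763	11
Alopecurus pratensis	23	Russia: Altai Krai	26172	Pr3	1928	7
Alopecurus pratensis	23	Russia: Altai Krai	26172	Pr4	1863	7
Alopecurus pratensis	23	Russia: Altai Krai	26172	Pr5	1416	5
Alopecurus pratensis	23	Russia: Altai Krai	26172	Pr6	1049	4
Alopecurus pratensis	M5	Russia: Karachay-Cherkessia, Teberda	22148	Pr5	5359	24
Alopecurus pratensis	M5	Russia: Karachay-Cherkessia, Teberda	22148	Pr1	4775	21
Alopecurus pratensis	M5	Russia: Karachay-Cherkessia, Teberda	22148	Pr7	3539	16
Alopecurus pratensis	M6	Russia: Arkhangelsk Oblast, Solovetsky Islands	15362	Pr5	3153	21
Alopecurus pratensis	M6	Russia: Arkhangelsk Oblast, Solovetsky Islands	15362	Pr1	1732	11
Alopecurus pratensis	M6	Russia: Arkhangelsk Oblast, Solovetsky Islands	15362	Pr8	1041	7
Alopecurus pratensis	L30	Russia: Altai Republic	14946	Pr1	2965	20
Alopecurus pratensis	L30	Russia: Altai Republic	14946	Pr2	2863	19
Alopecurus pratensis	L30	Russia: Altai Republic	14946	Pr5	1485	10
Alopecurus pratensis	L30	Russia: Altai Republic	14946	Pr4	1228	8
Alopecurus pratensis subsp. alpestris	L15	Russia: Komi Republic	25290	Pa1	9301	37
Alopecurus pratensis subsp. alpestris	L15	Russia: Komi Republic	25290	Pr1	2889	11
Alopecurus pratensis subsp. alpestris	L15	Russia: Komi Republic	25290	Pr5	1903	7
Alopecurus pratensis subsp. alpestris	L15	Russia: Komi Republic	25290	Pr4	1611	5
Alopecurus vlassowii	25	Russia: Altai Republic	21628	Vl1	5248	24
Alopecurus vlassowii	25	Russia: Altai Republic	21628	Br	2279	11
Alopecurus vlassowii	25	Russia: Altai Republic	21628	Vl2	1006	5
Limnas stelleri	M17	Russia: Irkutsk Oblast	1704	L1	364	21
Limnas stelleri	M17	Russia: Irkutsk Oblast	1704	L2	303	18
Limnas stelleri	M17	Russia: Irkutsk Oblast	1704	L3	195	11
Limnas stelleri	M17	Russia: Irkutsk Oblast	1704	L4	145	9
Limnas stelleri	M17	Russia: Irkutsk Oblast	1704	L5	80	5
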