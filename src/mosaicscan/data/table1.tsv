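subject_id	status	gene	mutation	mutation_type	af	tissues	age_years	sex	skin	brain	heart	kidney_lung	familial
P3	heterozygous	TSC2	c.848+1G>A	splice	0.50	blood,saliva	31	F	4	2	0	1	yes
P10	heterozygous	TSC2	c.226-12T>A	splice	0.50	blood,saliva	5	F	2	1	0	0	no
P11	heterozygous	TSC2	c.4660C>T	nonsense	0.50	blood	8	F	4	3	1	1	no
P18	heterozygous	TSC2	c.976-15G>A	splice	0.50	blood,saliva	2	F	1	1	0	0	no
P21	heterozygous	TSC2	c.5238_5255delCATCAAGCGGCTCCGCCA	indel	0.50	blood,saliva	24	M	4	4	1	1	no
P25	heterozygous	TSC1	c.1498C>T	nonsense	0.50	saliva	19	F	2	2	0	0	yes
P29	heterozygous	TSC1	c.-234-?_*1+?del	large_del	0.50	blood	26	F	3	3	1	0	no
P33	heterozygous	TSC2	c.-106-722_-85del	large_del	0.50	saliva	8	M	2	2	1	1	no
P37	heterozygous	TSC2	c.976-15G>A	splice	0.50	blood	7	F	1	2	1	1	no
P38	heterozygous	TSC1	c.664-15A>G	splice	0.50	saliva	1	M	1	2	0	0	yes
P43	heterozygous	TSC2	c.1432_1436delCAGTT	indel	0.50	saliva	27	F	3	2	0	1	no
P46	heterozygous	TSC2	c.481+5G>A	splice	0.50	blood,saliva	13	F	3	2	1	1	no
P52	heterozygous	TSC2	c.5018_5020delCA	indel	0.50	blood,saliva	1	M	1	2	1	0	no
P1	heterozygous	TSC2	c.849-15G>A	splice	0.50	blood	5	M	2	3	1	1	no
P24	heterozygous	TSC1	c.913+3A>T	splice	0.50	blood,saliva	10	M	2	1	0	0	yes
P34	heterozygous	TSC2	c.3611-9_3611-34delinsCC	splice	0.50	blood,saliva	22	F	3	3	0	1	no
P35	heterozygous	TSC2	c.1717-23T>G	splice	0.50	blood	14	M	2	1	1	0	no
P36	heterozygous	TSC2	c.1362-10C>A	splice	0.50	saliva	30	M	2	2	0	0	yes
P41	heterozygous	TSC2	c.2221-126C>T	splice	0.50	blood,saliva	15	F	2	4	0	0	no
P8	mosaic	TSC2	c.976-15G>A	splice	0.34	saliva	7	F	3	2	0	1	no
P53	mosaic	TSC1	c.1776delG	indel	0.30	blood,saliva	22	M	3	2	0	1	no
P12	mosaic	TSC2	c.3610+1G>T	splice	0.22	blood	4	M	1	2	0	0	no
P39	mosaic	TSC2	c.3884-?_PKD1:c.11270-?del	large_del	0.17	blood,saliva	18	F	4	2	0	0	no
P2	mosaic	TSC1	c.2689C>T	nonsense	0.15	blood	20	M	3	3	1	0	no
P4	mosaic	TSC2	c.4943T>C	missense	0.081	blood	9	M	2	2	1	0	no
P49	mosaic	TSC2	c.848+281C>T	splice	0.069	angiofibroma,blood,saliva,normal_skin	33	M	1	1	0	0	no
P22	mosaic	TSC2	c.226-12T>A	splice	0.059	fetal_tissue			0	1	1	0	no
P30	mosaic	TSC2	c.1413_1414delTG	indel	0.053	blood,normal_skin	33	M	2	0	0	1	no
P6	mosaic	TSC1	c.2111_2112delAT	indel	0.047	blood,normal_skin	4	M	1	2	1	0	no
P45	mosaic	TSC2	c.4051G>T	nonsense	0.044	saliva	19	F	2	0	0	1	no
P26	mosaic	TSC2	c.1717-247_CASKIN1:c.1417-380del	large_del	0.040	saliva	6	F	2	3	0	0	no
P5	mosaic	TSC1	c.2374C>T	nonsense	0.033	blood	57	F	2	0	0	1	yes
P15	mosaic	TSC2	c.4238insGGTTAAG	indel	0.032	blood	40	F	2	1	0	2	no
P9	mosaic	TSC2	c.1717-4103_3356del	large_del	0.030	saliva	1	F	1	2	1	0	no
P27	mosaic	TSC2	c.2356_2362delCGCGAGA	indel	0.030	blood,ungual_fibroma,angiofibroma,normal_skin	34	M	2	3	0	1	no
P28	mosaic	TSC2	c.2098-86_4493+31del	large_del	0.030	saliva	8	F	3	3	0	1	no
P16	mosaic	TSC2	c.1108C>T	nonsense	0.027	blood,saliva	2	M	1	2	1	0	no
P13	mosaic	TSC2	c.3685C>T	nonsense	0.017	blood	14	M	1	3	0	0	no
P20	mosaic	TSC2	c.5228G>A	missense	0.014	blood	30	M	2	1	0	1	no
P31	mosaic	TSC2	c.1831C>T	missense	0.012	saliva	18	F	2	1	1	1	no
P32	mosaic	TSC2	c.4850-1G>A	splice	0.0071	blood	17	F	3	2	1	0	no
P17	mosaic	TSC2	c.2647C>T	nonsense	0.0069	blood,angiofibroma	2	F	1	1	1	0	no
P51	mosaic	TSC2	c.4180_4181delCT	indel	0.0021	blood,saliva,angiofibroma	34	F	1	1	0	1	yes
P14	mosaic	TSC2	c.976-15G>A	splice		angiofibroma,normal_skin	23	M	1	1	0	1	no
P42	mosaic	TSC2	c.4530_4537delTGGCGACG	indel		angiofibroma,normal_skin	25	F	1	1	0	1	no
P7	persistent_NMI	none		none			11	M	1	1	0	0	no
P19	persistent_NMI	none		none			33	F	2	0	0	1	no
P23	persistent_NMI	none		none			9	M	1	1	0	0	no
P40	persistent_NMI	none		none			33	M	4	2	0	1	no
P44	persistent_NMI	none		none			20	F	0	2	0	1	no
P47	persistent_NMI	none		none			1	M	1	3	0	0	no
P48	persistent_NMI	none		none			4	M	1	2	0	0	no
P50	persistent_NMI	none		none			23	F	0	1	0	1	no
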