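level_code	name	cultivated_representative	db_size	accession	habitat
0	CuMMO		6628
0.1	MOB_like
0.1.1	TypeI
0.1.1.1	TypeIa
0.1.1.1.1	Mbacter	Methylobacter tundripaludum SV96	552	AJ414658	Arctic wetland
0.1.1.1.2	Mmicrobium_jap	Methylomicrobium japanense	28	AB253367	Marine mud
0.1.1.1.3	Mmicrobium_pel	Methylomicrobium pelagicum IR1	25	U31652	Upland soils
0.1.1.1.4	Mmonas	Methylomonas methanica	396	U31653	Lake sediments
0.1.1.1.5	Msarcina	Methylosarcina quisquilarum	517	AF177326	Landfill soil
0.1.1.1.6	Msoma	Methylosoma difficile LC2	4	DQ119047	Lake sediment
0.1.1.1.7	Mbacter_or_Mmonas		2	AY236078	Movile cave
0.1.1.1.8	Deep_sea_1		46	AM283467	Marine deep sea
0.1.1.1.9	Deep_sea_3		191	FJ858316	Marine deep sea
0.1.1.1.10	LP20		51	AB064377	Aquifer
0.1.1.1.11	Landfill_cluster_2		4	EU275117	Landfill soil
0.1.1.1.12	Lake_cluster_1		72	EF623667	Freshwater lakes
0.1.1.1.13	RPC_2		148	FN600101	Rice field soil
0.1.1.1.14	PS_80		8	AF211872	Marine
0.1.1.1.15	Aquifer_cluster		53	AM410175	Aquifer
0.1.1.2	TypeIb
0.1.1.2.1	Mcaldum	Methylocaldum tepidum	98	U89304	Agricultural soil
0.1.1.2.2	Mcoccus	Methylococcus capsulatus Bath	244	L40804	Aquatic environments
0.1.1.2.3	Mthermus	Methylothermus thermalis	36	AJ829010	Hot spring
0.1.1.2.4	JRC_4	Methylogaea oryzae	27	EU359002	Rice field soil
0.1.1.2.5	Deep_sea_4		26	GU584280	Marine deep sea
0.1.1.2.6	Deep_sea_5		155	EU417471	Marine deep sea
0.1.1.2.7	FWs		100	AF211878	Freshwater lakes
0.1.1.2.8	JRC_3		29	AB222881	Rice field soil
0.1.1.2.9	Lake_cluster_2		74	AF211879	Freshwater lakes
0.1.1.2.10	LWs		83	DQ067069	Freshwater lakes
0.1.1.2.11	OSC		18	AJ317928	Organic soil
0.1.1.2.12	RPC_1		67	FN599957	Rice field soil
0.1.1.2.13	RPCs		166	FJ845814	Rice field soil
0.1.1.3	TypeIc
0.1.1.3.1	Ncoccus	Nitrosococcus oceani	83	U96611	Marine
0.1.1.3.2	USCg		185	AJ579667	Upland soils
0.1.1.3.3	JR2		68	AY654695	Upland soils
0.1.1.3.4	JR3		65	AY654702	Upland soils
0.1.2	TypeII
0.1.2.1	TypeIIa
0.1.2.1.1	Msinus	Methylosinus trichosporium 33/1	70	AJ459007	Various
0.1.2.1.2	Mcystis	Methylocystis sp. strain SC2	1085	AJ431386	Various
0.1.2.1.3	Msinus_Mcystis	Methylosinus trichosporium str. KS21	79	AJ431388	Various
0.1.2.2	TypeIIb
0.1.2.2.1	Mcapsa	Methylocapsa acidiphila B2	27	AJ278727	Sphagnum bog
0.1.2.2.2	MO3		23	AF283229	Landfill soil
0.1.2.2.3	pmoA2	Methylocystis sp. strain SC2	45	AJ431387	Various
0.1.2.2.4	USCa		888	AF148521	Upland soils
0.1.3	pXMO_like
0.1.3.1	TUSC_like
0.1.3.1.1	Verr_1	Methylacidiphilum infernorum	3	EU223859	Geothermal soil
0.1.3.1.2	Verr_2	Methylacidiphilum infernorum	3	EU223862	Geothermal soil
0.1.3.1.3	Verr_3	Methylacidiphilum infernorum	3	EU223855	Geothermal soil
0.1.3.1.4	TUSC		101	AJ868282	Various
0.1.3.1.5	NC10	Cand. Methylomirabilis oxyfera	33	JX262154	Freshwater sediment
0.1.3.2	RA21_like
0.1.3.2.1	RA21		157	AF148522	Rice field soil
0.1.3.2.2	M84_P22		9	AJ299963	Rice field soil
0.1.3.2.3	gp23		1	AF264137	Upland soils
0.1.3.2.4	Alkane_1	Methylococcaceae ET-SHO	2	AB453961	Marine
0.1.3.2.5	Alkane_2	Methylococcaceae ET-HIRO	2	AB453962	Marine
0.1.3.2.6	MR1		7	AF200729	Upland soils
0.1.3.3	M84_P105_like
0.1.3.3.1	M84_P105	Methylomonas methanica	34	EU722433	Various
0.1.3.4	Crenothrix_like
0.1.3.4.1	Crenothrix	Crenothrix polyspora (enrichment)	69	DQ295904	Freshwater
0.1.3.4.2	Crenothrix_rel		160	AJ868245	Various
0.2	AOB_like	Nitrosospira multiformis	206	AF042171	Various
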