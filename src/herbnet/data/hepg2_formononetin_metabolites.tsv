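metabolite	formula	mz	rt_min	hmdb	vip	p_value	fc	trend	mode
L-Lysine	C6H14N2O2	147.1128	1.103	HMDB0000182	1.073	1.70e-2	2.36	up	pos
Choline	C5H14NO	105.1075	1.285	HMDB0000097	5.457	1.46e-2	3.90	up	pos
L-Serine	C3H7NO3	106.0926	1.287	HMDB0000187	1.766	3.60e-2	6.13	up	pos
Citrulline	C6H13N3O3	176.1031	1.295	HMDB0000904	1.629	3.93e-3	127.97	up	pos
L-Arginine	C6H14N4O2	175.1190	1.296	HMDB0000517	1.308	1.12e-3	0.06	down	pos
L-Threonine	C4H9NO3	120.0658	1.304	HMDB0000167	1.046	1.02e-2	0.12	down	pos
N-Acetylneuraminic acid	C11H19NO9	308.0993	1.319	HMDB0000230	1.226	1.74e-2	0.43	down	neg
Asymmetric dimethylarginine	C8H18N4O2	203.1504	1.328	HMDB0001539	1.134	5.37e-3	18.90	up	pos
Uridine diphosphate-N-acetylglucosamine	C17H27N3O17P2	606.0758	1.639	HMDB0000290	1.183	4.92e-5	0.05	down	neg
L-Valine	C5H11NO2	118.0865	1.941	HMDB0000883	6.734	9.46e-4	2.76	up	pos
dGDP	C10H15N5O10P2	426.0231	1.968	HMDB0000960	2.681	1.33e-3	0.03	down	neg
L-Methionine	C5H11NO2S	150.0584	2.023	HMDB0000696	5.192	2.34e-3	2.51	up	pos
L-Isoleucine	C6H13NO2	132.1021	2.081	HMDB0000172	1.996	2.61e-2	0.32	down	pos
Glutathione	C10H17N3O6S	306.0770	2.084	HMDB0062697	2.849	9.29e-3	0.07	down	neg
Oxoglutaric acid	C5H6O5	145.0981	2.102	HMDB0000208	4.288	1.57e-3	0.20	down	neg
Hypoxanthine	C5H4N4O	137.0459	2.181	HMDB0000157	8.273	4.04e-3	148.68	up	pos
5-Oxoproline	C5H7NO3	130.0501	2.254	HMDB0000267	2.655	1.59e-3	5.92	up	pos
Acetaminophen	C8H9NO2	152.0707	2.287	HMDB0001859	1.962	3.85e-4	2.81	up	pos
Niacinamide	C6H6N2O	123.0556	2.338	HMDB0001406	4.396	1.61e-2	2.61	up	pos
Xanthine	C5H4N4O2	153.0408	2.433	HMDB0000292	2.371	4.51e-3	184.22	up	pos
N-Acetyl-L-aspartic acid	C6H9NO5	174.0399	2.524	HMDB0000812	2.366	2.13e-2	0.19	down	neg
Isocitric acid	C6H8O7	191.0191	2.558	HMDB0000193	1.904	4.84e-3	0.13	down	neg
L-Tyrosine	C9H11NO3	182.0812	2.590	HMDB0000158	8.759	1.59e-3	2.78	up	pos
Spermine	C10H26N4	203.2231	2.601	HMDB0001256	1.816	2.70e-3	51.58	up	pos
Uracil	C4H4N2O2	113.0350	2.624	HMDB0000300	1.159	2.42e-2	112.62	up	pos
L-Glutamate	C5H9NO4	148.0605	2.756	HMDB0000148	1.631	3.03e-2	0.05	down	pos
L-Glutamine	C5H10N2O3	147.0765	2.881	HMDB0000641	1.761	3.05e-2	7.46	up	pos
L-Cysteine	C3H7NO2S	120.1580	2.909	HMDB0000574	1.099	2.99e-2	0.01	down	neg
L-Norleucine	C6H13NO2	132.1020	2.931	HMDB0001645	14.419	3.20e-3	2.52	up	pos
Triethanolamine	C6H15NO3	150.1126	3.208	HMDB0032538	1.102	1.05e-4	2.10	up	pos
L-Proline	C5H9NO2	116.0710	3.267	HMDB0000162	2.820	2.38e-2	2.39	up	pos
Spermidine	C7H19N3	146.1652	4.531	HMDB0001257	6.166	3.30e-4	4.68	up	pos
Oxidized glutathione	C20H32N6O12S2	611.1457	4.960	HMDB0003337	4.990	1.79e-3	0.14	down	neg
L-Phenylalanine	C9H11NO2	166.0863	5.044	HMDB0000159	10.928	6.97e-3	2.15	up	pos
N'-Formylkynurenine	C11H12N2O4	237.0871	5.046	HMDB0001200	1.027	6.80e-5	6.34	up	pos
Adenine	C5H5N5	136.0619	5.128	HMDB0000034	2.159	9.75e-3	12.75	up	pos
N-Formyl-L-methionine	C6H11NO3S	176.0379	5.258	HMDB0001015	1.437	8.47e-4	2.80	up	neg
Pantothenic acid	C9H17NO5	218.1032	5.333	HMDB0000210	1.190	3.19e-4	2.46	up	neg
8-Isoprostaglandin E2	C20H32O5	351.2183	8.836	HMDB0005844	1.806	4.87e-2	3.11	up	neg
Glycoursodeoxycholic acid	C26H43NO5	448.3076	11.325	HMDB0000708	1.338	1.85e-2	0.07	down	neg
8,9-DiHETrE	C20H34O4	339.4816	18.790	HMDB0002311	1.830	5.31e-3	0.26	down	pos
L-Palmitoylcarnitine	C23H46NO4	399.3280	22.009	HMDB0000222	1.753	9.76e-5	0.21	down	neg
Eicosapentaenoic acid	C20H30O2	301.2179	23.755	HMDB0001999	1.468	3.24e-2	14.10	up	neg
Arachidonic acid	C20H32O2	303.2335	25.677	HMDB0001043	3.689	1.12e-2	12.90	up	neg
Palmitic acid	C16H32O2	255.2331	27.686	HMDB0000220	1.442	2.94e-2	6.08	up	neg
Oleic acid	C18H34O2	281.2491	28.297	HMDB0000207	1.925	3.27e-3	4.13	up	neg
Stearic acid	C18H36O2	283.2647	30.628	HMDB0000827	1.510	4.62e-2	4.64	up	neg
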