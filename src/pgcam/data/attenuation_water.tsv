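# pgcam attenuation table v1: water
# density_g_cm3 = 1.0
# Compton: closed-form Klein-Nishina x electron density (exact); photoelectric: Z^4.5 power law anchored at sigma_pe(Pb,100keV)=1750 b; pair: Z^2 scaling of standard-compilation water anchors. Coherent scattering excluded. See scripts/make_attenuation_tables.py
# E_keV	mu_photo_per_mm	mu_compton_per_mm	mu_pair_per_mm
30	0.0061320897	0.019973318	0
32.455614	0.0048428696	0.019814271	0
35.112229	0.0038246972	0.019646013	0
37.986298	0.0030205869	0.019468287	0
41.095621	0.002385534	0.019280864	0
44.459454	0.0018839956	0.019083558	0
48.098629	0.0014879015	0.01887622	0
52.035684	0.0011750828	0.018658753	0
56.295003	0.00092803153	0.018431115	0
60.902962	0.00073292074	0.018193322	0
65.888101	0.00057883034	0.017945452	0
71.281292	0.00045713615	0.017687656	0
77.115937	0.00036102714	0.017420153	0
83.428169	0.00028512423	0.017143235	0
90.257082	0.00022517927	0.016857269	0
97.644966	0.00017783723	0.016562694	0
100	0.00016556642	0.01647184	0
105.63758	0.00014044845	0.016260021	0
114.28441	0.00011092035	0.015949825	0
123.63903	8.7600285e-05	0.015632746	0
133.75935	6.9183065e-05	0.015309472	0
144.70806	5.463791e-05	0.014980741	0
156.55297	4.3150751e-05	0.014647323	0
169.36742	3.407867e-05	0.014310013	0
183.23079	2.6913917e-05	0.013969619	0
198.22892	2.1255494e-05	0.013626948	0
214.45471	1.6786706e-05	0.013282798	0
232.00865	1.3257443e-05	0.012937944	0
250.99944	1.0470177e-05	0.012593128	0
271.54469	8.2689109e-06	0.012249054	0
293.77166	6.5304422e-06	0.011906376	0
317.81798	5.1574719e-06	0.011565694	0
343.83259	4.073157e-06	0.011227554	0
371.97659	3.2168101e-06	0.010892442	0
402.42429	2.540503e-06	0.010560784	0
435.36425	2.0063837e-06	0.010232955	0
471.00046	1.5845584e-06	0.009909273	0
500	1.3245314e-06	0.0096663983	0
509.55364	1.2514184e-06	0.00959001	0
511	1.2408222e-06	0.0095785934	0
551.26254	1.0661895e-06	0.0092753951	0
596.38547	9.1095569e-07	0.0089656204	0
645.20189	7.7832343e-07	0.0086608474	0
698.01411	6.6500201e-07	0.0083612127	0
755.14922	5.6817983e-07	0.0080668339	0
816.96105	4.8545465e-07	0.007777814	0
883.83241	4.1477399e-07	0.0074942459	0
956.17745	3.5438422e-07	0.0072162162	0
1000	3.2400474e-07	0.0070603652	0
1022	3.1020556e-07	0.0069853431	0
1034.4442	3.02787e-07	0.0069438073	8.9368787e-09
1119.1174	2.5870217e-07	0.0066770994	5.4430907e-07
1210.7214	2.2103596e-07	0.0064161716	2.0553882e-06
1309.8235	1.8885382e-07	0.0061611022	4.2805031e-06
1417.0376	1.6135731e-07	0.0059119682	7.785704e-06
1533.0275	1.3786419e-07	0.0056688449	1.312001e-05
1658.5116	1.177916e-07	0.0054318044	1.8110289e-05
1794.2671	1.0064152e-07	0.0052009148	2.4998651e-05
1941.1346	8.5988435e-08	0.0049762383	3.4507046e-05
2100.0239	7.5482494e-08	0.0047578296	4.4327406e-05
2271.9188	6.9771437e-08	0.004545735	5.4490529e-05
2300	6.8919582e-08	0.0045131913	5.6275406e-05
2457.884	6.4492482e-08	0.0043399905	6.6983792e-05
2659.0711	5.9612937e-08	0.0041406209	8.2341436e-05
2876.7262	5.5102581e-08	0.0039476388	0.00010122019
3112.1972	5.0933482e-08	0.0037610439	0.00012033807
3366.9423	4.707982e-08	0.0035808222	0.0001377063
3642.5393	4.3517729e-08	0.0034069464	0.00015758128
3940.695	4.0225148e-08	0.0032393751	0.00018032478
4263.2559	3.7181686e-08	0.0030780534	0.00020068899
4400	3.6026145e-08	0.0030150599	0.00020894605
4612.2195	3.4368494e-08	0.0029229133	0.00022190142
4989.7472	3.176815e-08	0.002773874	0.00024535597
5250	3.0193341e-08	0.0026807625	0.00025941731
5398.177	2.936455e-08	0.0026308428	0.00026739676
5840.0383	2.7142808e-08	0.0024937159	0.0002913047
6100	2.5986072e-08	0.0024203062	0.000305
6318.0676	2.5089165e-08	0.0023623792	0.00031590338
6835.2254	2.3190902e-08	0.002236709	0.00034176127
7000	2.2645006e-08	0.0021997578	0.00035
7394.7145	2.1436262e-08	0.0021165738	0.00036591015
8000	1.981438e-08	0.0020018345	0.00039
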