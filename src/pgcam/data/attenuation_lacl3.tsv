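# pgcam attenuation table v1: lacl3
# density_g_cm3 = 3.86
# Compton: closed-form Klein-Nishina x electron density (exact); photoelectric: Z^4.5 power law anchored at sigma_pe(Pb,100keV)=1750 b; pair: Z^2 scaling of standard-compilation water anchors. Coherent scattering excluded. See scripts/make_attenuation_tables.py
# E_keV	mu_photo_per_mm	mu_compton_per_mm	mu_pair_per_mm
30	12.112862	0.061159191	0
32.455614	9.5662352	0.060672183	0
35.112229	7.5550151	0.060156971	0
37.986298	5.9666369	0.059612763	0
41.095621	4.7122019	0.059038868	0
44.459454	3.7215013	0.058434706	0
48.098629	2.9390871	0.057799828	0
52.035684	2.3211688	0.057133936	0
56.295003	1.8331627	0.056436898	0
60.902962	1.4477557	0.055708763	0
65.888101	1.1433773	0.054949777	0
71.281292	0.90299188	0.054160394	0
77.115937	0.71314546	0.053341286	0
83.428169	0.56321265	0.052493351	0
90.257082	0.44480195	0.05161771	0
97.644966	0.3512861	0.050715709	0
100	0.32704728	0.05043751	0
105.63758	0.27743116	0.04978891	0
114.28441	0.2191036	0.048839078	0
123.63903	0.17303892	0.047868165	0
133.75935	0.13665895	0.046878287	0
144.70806	0.10792756	0.045871698	0
156.55297	0.085236701	0.044850758	0
169.36742	0.067316405	0.0438179	0
183.23079	0.053163699	0.042775597	0
198.22892	0.04198648	0.041726324	0
214.45471	0.033159177	0.040672521	0
232.00865	0.02618774	0.039616561	0
250.99944	0.020681989	0.038560721	0
271.54469	0.016333776	0.037507151	0
293.77166	0.012899737	0.036457855	0
317.81798	0.010187676	0.035414673	0
343.83259	0.0080458035	0.034379273	0
371.97659	0.0063542413	0.033353142	0
402.42429	0.0050183157	0.032337593	0
435.36425	0.0039632572	0.031333765	0
471.00046	0.0031300159	0.030342636	0
500	0.0026163782	0.029598943	0
509.55364	0.0024719565	0.029365039	0
511	0.0024510256	0.029330081	0
551.26254	0.0021060694	0.028401674	0
596.38547	0.0017994324	0.02745313	0
645.20189	0.0015374407	0.026519901	0
698.01411	0.0013135942	0.025602407	0
755.14922	0.0011223391	0.024701006	0
816.96105	0.00095893008	0.023816014	0
883.83241	0.0008193129	0.022947716	0
956.17745	0.00070002354	0.022096376	0
1000	0.00064001425	0.021619154	0
1022	0.00061275639	0.021389432	0
1034.4442	0.00059810234	0.021262248	1.5801745e-07
1119.1174	0.00051102053	0.020445577	9.6242028e-06
1210.7214	0.00043661757	0.019646604	3.6342354e-05
1309.8235	0.00037304743	0.01886557	7.5685731e-05
1417.0376	0.00031873291	0.018102711	0.00013766295
1533.0275	0.00027232641	0.017358256	0.00023198151
1658.5116	0.00023267655	0.016632428	0.00032021714
1794.2671	0.00019879958	0.015925433	0.00044201374
1941.1346	0.00016985499	0.015237464	0.00061013646
2100.0239	0.00014910236	0.014568687	0.00078377519
2271.9188	0.00013782117	0.013919244	0.00096347449
2300	0.00013613848	0.013819593	0.00099503379
2457.884	0.00012739353	0.013289245	0.0011843742
2659.0711	0.00011775485	0.012678766	0.0014559204
2876.7262	0.00010884544	0.012087846	0.0017897252
3112.1972	0.00010061012	0.011516484	0.002127758
3366.9423	9.2997885e-05	0.010964638	0.0024348545
3642.5393	8.5961602e-05	0.010432222	0.0027862739
3940.695	7.9457688e-05	0.0099191112	0.0031884132
4263.2559	7.3445865e-05	0.009425137	0.003548483
4400	7.1163299e-05	0.0092322482	0.0036944803
4612.2195	6.7888901e-05	0.008950091	0.0039235508
4989.7472	6.275238e-05	0.008493726	0.0043382625
5250	5.9641622e-05	0.0082086144	0.0045868881
5398.177	5.8004492e-05	0.0080557582	0.0047279767
5840.0383	5.3615833e-05	0.0076358696	0.0051507051
6100	5.1330904e-05	0.0074110857	0.0053928586
6318.0676	4.9559222e-05	0.0072337105	0.0055856467
6835.2254	4.5809538e-05	0.006848903	0.0060428531
7000	4.4731216e-05	0.0067357566	0.0061885263
7394.7145	4.2343557e-05	0.0064810436	0.0064698417
8000	3.9139814e-05	0.0061297067	0.0068957864
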