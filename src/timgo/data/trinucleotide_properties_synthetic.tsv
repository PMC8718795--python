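# Synthetic stand-in trinucleotide property table: 12 standardized
# pseudo-physicochemical indices (seeded random values, mean 0 / sd 1
# across the 64 trinucleotides). Substitute a real index table with the
# same layout for production use.
oligo	tprop01	tprop02	tprop03	tprop04	tprop05	tprop06	tprop07	tprop08	tprop09	tprop10	tprop11	tprop12
AAA	-0.320771	-0.696383	-0.215092	1.063811	0.017388	0.756519	0.757324	0.446095	0.463161	0.924729	-0.207006	-0.297077
AAC	0.194332	-1.525062	1.951410	0.404709	0.743727	-0.000474	0.306737	-0.028847	-0.315652	1.021656	1.358009	-0.690379
AAG	0.981371	0.205824	2.449283	-2.354462	1.208238	-0.531103	-0.561225	-0.557426	0.375519	-0.205527	0.603768	0.538004
AAT	-1.322514	-0.395312	0.128710	-2.156248	-0.019452	-0.091697	-2.188343	-0.118608	-1.148317	-0.768294	1.385563	1.281391
ACA	-0.879618	0.887236	0.589814	0.176427	0.060539	-1.141476	-0.014623	1.076385	0.823892	2.115750	-1.107028	-2.187063
ACC	-0.082612	-0.464364	-0.346434	-1.200388	1.233922	1.115711	-0.163634	0.004407	-1.703105	2.631758	0.902560	-1.508094
ACG	1.593395	1.466029	-1.247243	-1.282101	-1.045164	-0.180815	0.041228	-0.252950	-0.679289	1.488273	0.180694	-0.590661
ACT	-0.165683	-1.022379	-0.632938	0.806055	1.595711	-1.824456	-1.833079	-0.581859	-1.413406	1.368484	-0.090918	-2.255066
AGA	-1.917699	0.506298	0.500401	-0.510277	-0.096158	-1.011004	-0.555055	1.084664	-0.533712	0.052231	-0.304689	1.186348
AGC	-1.627587	-0.294107	1.708803	0.093566	-0.369980	0.603761	-1.738486	-2.370506	-0.785944	0.862076	-0.240930	-0.746153
AGG	-0.472108	0.163640	-0.382873	-0.147719	0.245275	-1.924765	0.564721	-0.342119	-0.403755	0.905547	-0.369935	-0.252447
AGT	-1.647545	1.470394	-0.213850	-1.175009	-1.039995	-0.080176	0.771765	-0.419530	0.387656	0.274298	-1.329755	0.400536
ATA	0.141758	-0.450295	-0.399569	-0.607531	1.051374	-0.876290	1.052309	-1.191040	-0.857427	-0.134940	1.199368	-0.231721
ATC	1.033657	-0.612641	-0.444279	1.617997	-1.232558	0.653919	0.564325	0.890508	-0.741491	-1.691314	0.606187	0.600118
ATG	-1.509568	2.293231	0.481744	0.377661	-1.184008	-1.212706	-0.325558	-0.423479	-0.426310	-0.735778	-1.340706	-0.353261
ATT	1.058224	0.710026	-0.613925	0.492738	0.852271	0.009972	-1.005719	0.974197	0.048453	-0.203059	-0.502180	-0.751710
CAA	-0.395732	-1.164793	0.103695	-0.001570	0.497102	0.836556	0.547869	0.356569	0.777864	1.755291	-0.259899	-1.195716
CAC	0.105120	0.314420	0.679113	-0.308363	1.777674	0.409086	0.226249	-0.643101	0.146606	0.345145	0.423149	-1.278081
CAG	-2.078859	-1.583874	-0.811477	1.525972	-0.089722	0.266951	1.330109	0.031743	1.751146	-2.471999	0.358698	2.511459
CAT	1.681591	-0.636525	-0.927529	1.571064	0.065518	0.167473	1.151916	-1.756767	0.697672	-0.978340	-0.581248	0.196631
CCA	0.671288	1.368492	0.500882	-0.471885	-1.499948	-1.650385	1.339692	1.569894	0.316417	0.082198	-1.932494	1.095310
CCC	-0.955304	-0.699663	0.307903	-1.344630	0.677607	0.167675	-2.383321	-0.093152	-0.148822	-1.553536	-1.321360	-1.318702
CCG	0.918946	0.809458	-0.849855	0.325575	-0.123218	1.191776	-0.256947	1.097546	0.585614	1.216823	0.881209	-0.720907
CCT	0.448295	-1.129999	-1.563493	0.443966	0.144223	0.745501	-0.149213	-0.201709	-0.176803	0.767311	0.468015	-0.022332
CGA	-0.232480	0.200029	-2.320332	0.718322	-0.509732	-0.367371	0.981618	-0.419333	-0.979833	-0.875964	0.575256	0.639086
CGC	0.803944	1.753959	-1.174623	-1.124166	0.496603	1.755437	1.220539	-2.090370	0.622319	0.262940	-1.618449	0.560749
CGG	-0.079157	0.251629	-0.974510	1.084350	0.942077	1.551019	-1.454706	-0.081594	0.237573	-0.180668	1.820662	0.979822
CGT	-0.869769	0.075720	0.046179	-1.198219	-0.177967	-0.641660	0.699592	1.054505	-0.035606	0.042319	-0.452265	-0.786646
CTA	-0.678740	-0.483353	-0.116233	-0.566345	-0.245129	-0.281195	0.797672	1.316522	-2.210784	-0.651424	-0.045353	-0.736751
CTC	-0.700565	-0.046402	0.792682	-0.569731	1.040341	0.680832	0.022952	0.068418	-2.141672	0.749178	-0.242099	0.479093
CTG	1.109696	-1.359124	0.137002	0.520519	-0.244061	1.927254	0.193059	0.856939	0.289183	-0.086221	-0.820456	0.268955
CTT	-1.141089	1.358453	-1.923418	-1.180694	-1.507354	-1.715594	-0.528203	0.113109	2.020011	-2.154168	1.716904	-0.926923
GAA	-1.307588	-0.012729	-0.327393	-0.175864	-0.555061	-0.631210	0.143395	0.764974	-0.780420	-0.293896	2.049070	0.030507
GAC	-0.638336	0.634066	1.385123	-1.386950	-1.795799	0.602450	-0.346576	0.556594	-0.652467	-0.353164	1.153470	0.920357
GAG	0.234500	0.461500	-0.017397	1.273394	0.532506	-1.612459	0.947157	-0.541908	-0.235349	-0.166394	0.820862	-1.139763
GAT	-0.965690	0.912943	-0.269509	-0.643318	-1.280641	-0.261199	-0.886518	0.087037	-0.639499	0.096923	0.496026	0.562496
GCA	-0.129020	-0.515594	0.039588	0.635531	-0.457453	2.530181	2.206155	0.158305	0.300539	-0.105460	-0.397642	-0.802976
GCC	0.332043	-1.230746	1.875342	0.524960	-1.187206	-0.853584	0.320923	-2.006674	1.023855	-0.354017	-1.732127	0.877497
GCG	-0.588188	0.287041	0.762543	0.871790	0.005328	0.373657	-0.548154	2.948768	-0.409967	-1.980067	-0.871354	0.702410
GCT	0.335452	-0.182670	0.421873	-0.375699	0.276357	-2.105468	0.955365	-1.070155	-0.828559	-0.145366	-0.420645	0.837087
GGA	1.941757	0.737755	2.109240	-0.600963	-1.517452	1.635935	-0.487733	0.561809	0.077515	0.656180	0.506371	-0.643449
GGC	-1.013885	-1.113539	0.409124	0.913975	-2.154829	-0.623100	0.401971	0.925570	-1.141659	1.438445	0.810326	-0.351388
GGG	0.443589	-0.131764	-1.068075	1.208780	-0.053870	-0.428528	-0.681561	-0.654655	0.345387	-0.410488	0.624454	-1.004947
GGT	1.283919	0.063023	-0.767361	0.505864	0.435516	-0.887167	0.458533	-0.672695	1.898056	-0.640014	-0.289106	0.097620
GTA	-0.640633	0.384162	-0.377987	1.347084	-0.470083	1.014162	-0.558198	1.137137	2.122171	-1.190552	0.157228	2.125906
GTC	0.382853	1.079796	-0.154247	0.187278	-0.636918	0.495526	0.642088	0.242937	1.405872	-0.740319	-0.164771	0.780327
GTG	-0.121963	1.844983	-1.555800	-1.508784	-1.220885	0.358085	0.886120	0.803427	0.408026	-0.915625	1.823782	-1.025643
GTT	0.761313	0.969601	0.558251	-0.331456	0.478762	-0.163648	-0.330148	-0.718924	1.170070	-0.352996	-1.188966	-0.055390
TAA	-0.827067	0.863359	0.343124	0.078251	0.285285	0.861317	-1.676081	-1.297657	0.313189	-0.587888	0.373573	-1.191778
TAC	-0.246020	-0.181046	-0.793822	-1.171429	-0.519268	0.889675	2.002679	-0.045282	-0.333491	1.230149	-1.078097	1.268717
TAG	-0.879299	-1.016391	-0.765708	-1.437780	0.497233	-0.486281	2.237775	-0.602784	0.455555	-0.725927	-2.038769	-0.073435
TAT	1.532069	1.714762	0.384126	-0.236314	-0.159136	0.063237	0.128743	1.197415	-0.348634	-1.121834	1.269032	-0.981313
TCA	0.215494	-0.932561	0.234873	-0.953372	1.723395	0.357659	-0.502745	-1.375234	0.089252	-0.322290	0.503122	-0.399807
TCC	-1.288984	-0.777218	-0.421752	0.451427	0.340075	-1.018764	-0.949462	-0.949576	0.666402	0.710879	-1.449249	-0.029813
TCG	1.156476	-1.001838	1.841476	-0.265637	2.199687	-0.335951	-1.851074	0.276648	-0.855240	-0.352818	-0.497289	1.452626
TCT	0.047820	-1.034325	-0.509829	-0.181189	-0.169698	0.275821	-1.023166	-0.552069	-0.425583	0.164162	0.499365	-0.922132
TGA	-0.969123	-1.267121	0.450426	0.397244	-0.743957	0.892075	0.881137	0.658149	-0.193933	-0.837313	-0.170298	1.527914
TGC	1.662342	1.122423	2.088793	2.585051	-1.859817	0.063213	-0.608691	-0.030534	-1.407347	0.367042	-1.690350	1.000813
TGG	-0.041449	0.179952	-0.745223	-0.437191	0.535853	0.366123	-0.466067	-0.343454	0.652337	-0.592001	-0.327560	-0.681833
TGT	0.835400	-1.403102	-1.438348	1.517596	1.984115	0.770067	-0.618231	-1.547570	0.506443	1.015424	1.527192	-0.416239
TTA	1.775589	-2.337074	-0.587386	0.103169	-0.355838	-0.803736	-0.477245	1.924884	-1.180937	0.132450	-0.110053	0.183093
TTC	1.382213	-0.220787	0.811872	-0.108546	0.519584	-1.373618	0.073569	-1.098662	3.277976	1.116402	1.186384	1.340877
TTG	1.077283	-0.658879	0.082974	0.555095	-0.339835	-0.751230	0.800951	1.050246	0.436369	-0.091807	-1.052604	0.408941
TTT	0.592913	1.491453	0.781144	1.634607	2.398909	1.478481	-0.486479	0.844823	-0.557084	1.177406	-0.034646	1.714906
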