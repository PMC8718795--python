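# Synthetic stand-in dinucleotide property table: 15 standardized
# pseudo-physicochemical indices (seeded random values, mean 0 / sd 1
# across the 16 dinucleotides). Substitute a real index table with the
# same layout for production use.
oligo	dprop01	dprop02	dprop03	dprop04	dprop05	dprop06	dprop07	dprop08	dprop09	dprop10	dprop11	dprop12	dprop13	dprop14	dprop15
AA	0.006524	0.180299	1.406522	0.978859	1.075768	1.310411	-1.110037	0.459356	0.041070	-1.438646	1.379415	-0.744265	1.250353	1.248729	0.777658
AC	0.478481	0.969162	2.041847	-2.818589	-0.806929	0.133625	-1.085425	-2.267569	0.386467	-1.764387	-1.233254	-0.557952	-0.447128	0.678735	-0.910935
AG	0.823610	0.676317	-1.548828	0.516041	-0.472917	0.167496	-1.110013	0.858205	0.627422	-1.211521	0.423009	-1.607474	-0.464955	-1.319615	-1.599169
AT	0.700878	1.436831	-0.778473	-0.762029	0.489981	-0.150960	1.436080	0.752082	0.815141	1.015175	1.498370	-0.948119	-0.666670	1.197474	0.266721
CA	-0.203085	-0.332935	0.326156	-0.574949	2.286152	-0.580661	1.443375	1.879043	-0.385967	0.812192	-1.072485	-1.123330	-1.977912	-0.238069	0.530022
CC	0.107557	-1.012658	0.405015	1.192948	-0.236113	0.570743	-0.649922	0.047160	0.951115	0.004746	0.167239	0.899132	0.795507	-0.528753	-1.245428
CG	0.834681	-2.179021	0.229353	-1.009222	0.281238	-1.977928	0.547383	1.000260	1.927842	-0.075860	0.256411	-0.223906	0.185324	1.838566	2.006978
CT	-0.535670	0.223330	0.286972	0.781575	-0.380758	0.567330	0.371518	-0.573516	0.193511	1.370581	-1.452363	-0.425578	0.091719	0.037501	-0.310836
GA	-0.549834	0.038014	-1.812639	-0.987872	-1.223225	0.449893	1.891049	-0.869343	-0.463390	-0.240305	0.489207	0.943895	0.227567	-0.460091	-0.486424
GC	0.632045	-0.142657	-0.161487	0.838643	0.626287	0.115804	-1.423901	1.073612	-2.038819	1.665686	0.318486	0.606804	-0.744312	-1.814270	1.484102
GG	1.652822	0.956784	-1.242079	0.442559	-0.035104	0.700447	0.165974	-0.747720	-1.942132	0.318751	-0.541192	1.381876	1.558936	-1.452393	-0.370731
GT	-3.063503	-0.980339	-0.463482	0.203884	0.650377	1.954730	-0.555589	-0.887466	-0.182389	-0.319793	0.859442	-1.367558	-0.201009	0.281878	-0.466092
TA	-0.050966	-0.228129	1.021407	-0.060866	-0.899913	0.377501	0.026218	-0.188746	-1.052331	-0.457301	-1.365696	1.589364	-0.596144	0.598150	-1.057034
TC	-0.734703	1.832250	-0.025085	0.543804	0.307367	-1.551816	-0.054445	-0.230999	0.260449	0.658179	-1.409705	0.638603	-1.319149	0.795621	0.788672
TG	0.266069	-1.058975	0.531251	0.802295	0.514818	-1.219538	-0.783567	-0.891141	0.791426	0.841090	1.122480	-0.215239	1.913273	-0.556113	-0.501144
TT	-0.364906	-0.378271	-0.216451	-0.087083	-2.177028	-0.867079	0.891302	0.586783	0.070586	-1.178586	0.560634	1.153748	0.394601	-0.307349	1.093640
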