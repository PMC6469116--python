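# Synthetic stand-in ERCC spike-in reference sheet.
# 92 transcripts, log-spaced concentrations over six decades,
# representative lengths 250-2000 nt. Not the commercial mix table;
# only within-mix ratios are ever used by the method.
transcript_id	length_nt	concentration	mix_label
ERCC-00001	1463	2.615667e-04	Mix1
ERCC-00002	676	3.543648e-04	Mix1
ERCC-00003	1021	4.230324e-05	Mix1
ERCC-00004	1747	4.338730e-06	Mix1
ERCC-00005	734	6.341585e-03	Mix1
ERCC-00006	937	1.835423e-08	Mix1
ERCC-00007	1932	3.823117e-07	Mix1
ERCC-00008	987	1.658747e-04	Mix1
ERCC-00009	667	7.196857e-08	Mix1
ERCC-00010	853	6.504094e-04	Mix1
ERCC-00011	330	7.963407e-06	Mix1
ERCC-00012	1682	1.000000e-08	Mix1
ERCC-00013	1169	5.312204e-08	Mix1
ERCC-00014	1313	2.550313e-03	Mix1
ERCC-00015	679	2.424462e-07	Mix1
ERCC-00016	1456	1.000000e-02	Mix1
ERCC-00017	1240	3.044504e-04	Mix1
ERCC-00018	692	1.461622e-05	Mix1
ERCC-00019	760	8.811603e-04	Mix1
ERCC-00020	593	2.968435e-03	Mix1
ERCC-00021	1604	3.727594e-06	Mix1
ERCC-00022	1786	7.017038e-07	Mix1
ERCC-00023	580	1.320928e-07	Mix1
ERCC-00024	1817	9.506529e-07	Mix1
ERCC-00025	1438	1.255744e-05	Mix1
ERCC-00026	615	1.224368e-04	Mix1
ERCC-00027	301	4.021570e-03	Mix1
ERCC-00028	1105	2.082962e-07	Mix1
ERCC-00029	1777	2.191086e-03	Mix1
ERCC-00030	1686	5.878016e-06	Mix1
ERCC-00031	1437	1.882458e-03	Mix1
ERCC-00032	1819	2.751442e-06	Mix1
ERCC-00033	729	1.106512e-06	Mix1
ERCC-00034	975	2.821951e-07	Mix1
ERCC-00035	854	1.134867e-07	Mix1
ERCC-00036	854	6.183136e-08	Mix1
ERCC-00037	601	1.078865e-05	Mix1
ERCC-00038	1362	7.381283e-03	Mix1
ERCC-00039	353	3.455107e-03	Mix1
ERCC-00040	708	3.368779e-08	Mix1
ERCC-00041	857	5.731150e-05	Mix1
ERCC-00042	1146	1.617302e-03	Mix1
ERCC-00043	890	6.841713e-06	Mix1
ERCC-00044	1301	2.894266e-08	Mix1
ERCC-00045	425	1.701254e-05	Mix1
ERCC-00046	1311	1.025626e-03	Mix1
ERCC-00047	688	8.376776e-08	Mix1
ERCC-00048	1649	9.037409e-05	Mix1
ERCC-00049	734	3.921088e-08	Mix1
ERCC-00050	1533	5.050062e-06	Mix1
ERCC-00051	1463	3.122522e-05	Mix1
ERCC-00052	277	1.354778e-08	Mix1
ERCC-00053	1116	6.670768e-05	Mix1
ERCC-00054	1599	4.124626e-04	Mix1
ERCC-00055	784	4.563948e-08	Mix1
ERCC-00056	267	1.051909e-04	Mix1
ERCC-00057	993	3.284608e-07	Mix1
ERCC-00058	484	4.923883e-05	Mix1
ERCC-00059	470	1.193777e-03	Mix1
ERCC-00060	617	2.136340e-08	Mix1
ERCC-00061	1511	1.576893e-08	Mix1
ERCC-00062	1366	1.425103e-04	Mix1
ERCC-00063	1888	1.930698e-04	Mix1
ERCC-00064	1727	9.750143e-08	Mix1
ERCC-00065	1125	1.789564e-07	Mix1
ERCC-00066	1026	5.179475e-07	Mix1
ERCC-00067	1621	1.537493e-07	Mix1
ERCC-00068	509	8.591439e-03	Mix1
ERCC-00069	995	1.499078e-06	Mix1
ERCC-00070	1743	4.680903e-03	Mix1
ERCC-00071	1915	4.449914e-07	Mix1
ERCC-00072	580	1.287924e-06	Mix1
ERCC-00073	1006	2.247234e-04	Mix1
ERCC-00074	1110	1.744851e-06	Mix1
ERCC-00075	1214	2.486591e-08	Mix1
ERCC-00076	1711	8.167477e-07	Mix1
ERCC-00077	1094	1.389495e-03	Mix1
ERCC-00078	894	9.269002e-06	Mix1
ERCC-00079	756	1.980174e-05	Mix1
ERCC-00080	862	5.448334e-03	Mix1
ERCC-00081	1085	7.764436e-05	Mix1
ERCC-00082	935	3.202540e-06	Mix1
ERCC-00083	1619	2.682696e-05	Mix1
ERCC-00084	1813	6.028646e-07	Mix1
ERCC-00085	1228	1.163949e-08	Mix1
ERCC-00086	531	3.634457e-05	Mix1
ERCC-00087	517	7.570436e-04	Mix1
ERCC-00088	1002	2.030918e-06	Mix1
ERCC-00089	1494	4.800856e-04	Mix1
ERCC-00090	1425	2.304822e-05	Mix1
ERCC-00091	342	5.587953e-04	Mix1
ERCC-00092	392	2.363885e-06	Mix1
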