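# SYNTHETIC residue scales: 48 seeded unit-norm random linear combinations
# of the z-scored classical scales in base_scales.tsv. They are stand-ins
# for a larger curated scale collection and carry no literature provenance.
name	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
SYN001	1.2208	0.0077	-1.6476	-0.8837	1.2715	-0.3028	-0.2594	0.4065	-0.7159	1.1968	1.5358	-0.9185	-0.1845	-0.6056	-1.8770	-0.1333	-0.0755	0.4919	1.1045	0.3684
SYN002	0.5369	-1.0523	-0.2023	0.1439	-0.5669	-0.0567	-0.4262	-0.7472	1.6550	-0.3515	-0.0565	0.3021	-0.2538	0.5514	0.6985	0.5057	0.6326	-0.2616	-1.0012	-0.0498
SYN003	1.6859	1.8728	-2.0176	-2.4323	0.9617	0.9486	-0.4204	0.9824	-2.0472	1.1693	0.9081	-0.6105	-0.2558	-0.9805	-2.5909	0.4839	0.9164	1.5140	0.2386	-0.3264
SYN004	-0.5098	0.1660	0.1587	-1.1868	-0.0186	1.3276	0.0504	0.3053	-0.7042	-0.1348	-0.9068	0.7889	0.4331	-0.2715	-0.4504	0.5141	0.0698	0.3283	-0.4949	0.5356
SYN005	0.0072	0.0093	0.3787	0.4432	-0.1076	-0.2985	0.6781	0.0002	-0.5019	-0.2304	-0.0286	0.2447	-0.1287	0.4176	-0.6186	-0.3570	-0.0060	0.2249	0.2532	-0.3800
SYN006	-0.1509	0.5217	-0.8974	-0.8295	0.8277	0.3101	-0.9200	2.1366	-1.5944	1.3263	0.2011	-0.6198	0.0418	-0.5651	-1.1511	-0.2354	-0.3671	1.6985	-0.1730	0.4398
SYN007	-0.3457	-0.8492	2.3505	2.1872	-1.9652	-0.0046	-0.2040	-1.4049	2.5816	-1.3029	-1.2886	0.7646	0.2271	0.7480	3.1108	0.3721	-0.2378	-1.3093	-2.2329	-1.1970
SYN008	0.9009	0.5446	-0.8814	-0.6274	1.1166	-0.7794	0.2231	0.4707	-0.8517	0.7064	1.0859	-0.7546	-1.6728	-0.3628	-0.5644	-0.6487	-0.0253	0.5859	1.4601	0.0744
SYN009	0.8795	0.4437	-1.4494	-0.8687	1.2735	-0.4500	0.1925	0.7501	-1.4296	0.9496	1.1146	-0.8884	-0.7478	-0.3574	-1.7093	-0.5445	0.0400	0.4617	2.0311	0.3089
SYN010	1.2547	0.9890	-0.6383	-0.4018	0.1510	0.7620	-0.6747	1.0080	-0.7959	0.7665	0.6333	-0.6241	-0.8429	-0.7198	-0.5937	0.3432	0.3624	1.3408	-1.4435	-0.8762
SYN011	0.8823	0.2526	-1.3050	-0.0777	1.5815	-0.4649	-1.0496	2.4898	-1.4387	1.8411	1.3856	-1.7128	-0.8481	-0.8734	-2.0271	-0.5614	-0.2310	1.7973	0.6250	-0.2656
SYN012	-0.9555	-1.6981	2.0045	2.1753	-1.4382	-1.2867	0.4664	-1.6033	2.9092	-1.5640	-1.1675	1.0276	-0.3979	1.4091	2.9852	-0.2286	-0.0483	-1.4942	-0.7188	-0.3762
SYN013	-0.6680	0.3402	-2.6040	-2.1622	1.8847	-1.2483	-0.3876	1.8424	-1.3278	1.5348	0.9279	-0.8805	-1.2522	-0.2892	-0.6825	-1.1028	-0.0416	1.5993	2.3308	2.1865
SYN014	-1.1486	-0.9033	-0.8671	-0.7242	1.2406	-1.1073	-0.4357	0.9872	0.2465	0.4254	0.0206	-0.5498	-0.5874	0.0847	0.0911	-0.7335	-0.0337	0.2087	2.0784	1.7074
SYN015	-0.9472	-0.0099	-1.1818	-0.4107	2.0309	-1.4947	0.2780	0.9865	-1.0114	1.0872	1.3461	-1.2134	-0.7222	-0.7347	-0.2647	-1.1241	-0.9943	-0.0876	3.0176	1.4506
SYN016	0.0143	0.2911	-2.2545	-2.2865	1.8554	-0.9410	-0.7349	1.4059	-0.8014	1.3535	0.8357	-1.0148	-0.6053	-0.4675	-1.3393	-0.6874	0.2702	1.2620	2.1625	1.6819
SYN017	-0.8444	0.2518	-0.6434	-1.3254	-0.4369	0.2216	-0.3064	-0.5881	0.7850	-0.3040	-0.7255	0.4646	0.7210	0.1686	1.1972	0.3420	0.4320	-0.4143	-0.0172	1.0218
SYN018	-0.0205	0.6728	-1.8691	-1.8272	1.4790	-0.3081	0.4247	0.4964	-1.6388	0.7372	0.7040	-0.1012	-0.0816	-0.6174	-1.9985	-0.3191	0.2404	0.4850	2.1638	1.3781
SYN019	0.5210	0.2362	0.2589	0.5137	0.0656	-1.3607	1.0865	-0.6741	0.7420	-0.0742	0.8149	-0.0443	-1.2901	0.1574	0.5352	-0.7835	-0.0757	0.3467	-0.2370	-0.7385
SYN020	-0.4692	-0.4277	0.0154	0.3969	0.5507	-1.3655	0.0971	0.1421	0.0955	0.0769	0.1352	-0.2868	-0.3766	0.3952	0.1184	-0.7685	-0.2936	-0.2891	1.7258	0.5280
SYN021	0.0783	1.1120	-0.7923	-1.1856	0.0987	1.1679	-1.2669	1.6839	-1.3208	0.5142	-0.3377	-0.2688	-0.0018	-0.4660	-0.9989	0.6312	0.8566	1.7081	-1.1383	-0.0737
SYN022	-0.5067	0.7651	-1.2198	-0.6688	0.6878	-0.4753	0.0168	0.6674	-1.4230	0.6578	0.6633	-0.3994	-0.1543	-0.1766	-0.1506	-0.3704	-0.3117	0.3465	1.1850	0.8670
SYN023	0.7715	-0.2419	-0.6393	-0.5692	0.1388	0.7099	-0.3369	-0.2114	-0.6311	-0.1212	0.1861	-0.3458	1.0746	0.3487	-1.9179	0.6410	0.6831	-0.5518	1.0740	-0.0612
SYN024	-0.0446	0.4017	-1.0854	-0.6476	1.4846	-1.3138	0.7014	0.6239	-0.5337	0.9951	1.1816	-0.8769	-0.4733	-0.6871	-1.0171	-1.2425	-0.5037	0.6672	1.6539	0.7163
SYN025	0.9139	0.0581	-0.3169	-0.5775	0.2356	0.5310	-0.2300	-0.1193	-0.3119	0.4698	0.3141	-0.2245	0.5996	-0.3226	-0.9463	0.2060	-0.2423	-0.0469	0.0630	-0.0532
SYN026	0.7482	1.0948	-0.4714	-0.4941	0.1982	0.4585	0.3397	-0.2223	-1.2963	0.1751	0.6603	-0.1551	0.1487	-0.4134	-1.1892	0.1050	0.0709	0.2498	0.1960	-0.2032
SYN027	0.6111	1.8139	-1.6970	-2.2968	0.6982	1.7794	-0.4946	1.2397	-2.3777	1.0553	0.3270	-0.1760	0.4840	-1.3487	-2.1014	0.6161	0.3959	1.5223	-0.5068	0.4561
SYN028	0.8706	0.5500	-0.5902	-0.3195	0.5136	0.3429	-0.1604	-0.0683	-0.7826	0.4911	0.7078	-0.6391	0.0263	-0.5836	-0.8064	0.2408	-0.1006	-0.5187	1.0974	-0.2712
SYN029	-0.4356	-0.3691	0.1023	-0.3782	0.1066	-0.5897	-0.0547	-0.4853	0.6623	-0.2598	-0.2150	0.0426	0.1405	0.4473	0.4284	-0.1752	0.0157	-0.4764	0.8913	0.6020
SYN030	-0.8425	0.2599	0.2715	-0.8767	-0.7671	0.3639	0.1858	-0.3468	0.1175	-0.6343	-1.2231	0.9633	0.0571	0.6471	1.2170	0.1110	0.2677	-0.0317	-0.2716	0.5319
SYN031	-0.9197	0.3986	0.1206	-0.1908	0.5217	-0.8013	0.4485	-0.0500	-0.6543	-0.2138	0.1209	-0.0176	0.1594	0.1011	0.1513	-0.4404	-0.3300	-0.2201	1.1823	0.6335
SYN032	-0.9158	0.7219	-1.4610	-1.5493	1.4587	-0.1591	-0.5255	1.8901	-1.6051	1.3414	0.5764	-0.7867	-0.4071	-0.8207	-0.2354	-0.3948	-0.5461	1.1468	1.0058	1.2657
SYN033	-0.8926	-0.7912	2.1462	1.9662	-1.3390	-0.5212	1.5331	-2.3037	1.6490	-1.8774	-0.7031	1.2633	-0.1164	0.8882	2.5292	-0.0342	-0.3840	-1.9560	-0.6289	-0.4275
SYN034	0.9488	-0.0633	-0.4687	0.1758	0.5805	-0.5879	0.4046	-0.0198	-0.1345	0.5369	0.9662	0.0612	-1.5363	-0.4253	-0.1770	-0.3092	-0.2328	0.5633	-0.1831	-0.0993
SYN035	-1.2057	-0.0509	-0.0834	0.9261	0.8892	-2.0863	0.7498	0.5223	-0.0151	0.4238	0.7687	-0.7231	-0.8537	-0.0379	1.0300	-1.4581	-0.9496	-0.0894	1.7261	0.5172
SYN036	-0.1756	-0.5736	0.4634	0.2895	0.0038	-0.3030	0.8746	-0.9210	0.1647	-0.8404	0.0837	0.3615	0.0222	0.5965	-0.1382	0.0757	0.1885	-0.8343	0.6966	-0.0345
SYN037	-0.3055	0.1421	0.5386	0.5801	-0.8574	0.1850	0.4417	-0.3464	-0.0257	-0.4748	-0.3995	0.4088	0.4522	0.5438	0.6012	0.0438	-0.0711	-0.2275	-0.7767	-0.4528
SYN038	1.2546	0.5565	-0.3045	-0.5278	0.4817	0.7249	-0.6612	0.8112	-1.2229	0.4935	0.2970	-0.7444	0.3086	-0.3727	-2.1315	0.2053	0.3612	0.6863	0.3765	-0.5922
SYN039	0.5785	0.9727	-1.1518	-1.2123	1.6672	-0.4509	0.4181	1.2036	-2.1982	1.3574	1.2526	-0.6531	-0.9677	-0.7400	-1.8741	-0.5810	-0.5189	1.0870	1.6250	0.1860
SYN040	0.2048	-0.9428	0.4543	0.8749	0.0060	-0.5393	0.4816	-0.9737	0.8138	-0.0715	0.2372	0.1549	0.0688	0.1348	0.6487	-0.1264	-0.7454	-1.3682	0.7651	-0.0778
SYN041	0.0418	-0.2380	1.5476	1.7634	-0.9702	-0.6045	0.9888	-0.9139	0.8995	-0.8397	-0.3013	0.6020	0.0293	0.5727	0.5582	-0.3376	-0.1435	-0.3226	-1.0978	-1.2341
SYN042	-0.0098	-2.3764	2.7138	2.5178	-2.0186	-0.6792	0.7950	-2.5207	3.3745	-2.2293	-1.2650	1.1467	-0.0877	2.0109	2.6665	0.0789	0.1457	-2.1009	-1.0891	-1.0730
SYN043	-0.5880	-0.9854	1.1284	1.2540	-0.6077	-0.3818	0.3410	-0.3909	0.7814	-0.7922	-0.6424	0.6028	-1.0292	0.7113	1.7278	-0.2957	-0.2574	-0.4868	-0.1805	0.0911
SYN044	-0.5980	0.7710	-1.0438	-1.5106	1.2974	-0.1465	0.3427	1.2127	-2.1917	0.5778	0.3687	-0.4866	-0.4286	-0.1970	-1.0741	-0.6013	-0.1890	0.7005	2.1098	1.0866
SYN045	2.3597	1.1372	-1.1787	-0.9468	0.6384	0.8200	0.3842	0.2742	-1.5898	0.9486	1.3882	-0.5108	-0.5728	-0.8395	-2.6368	0.2328	0.3854	1.0880	-0.2734	-1.1080
SYN046	-0.6120	-1.4875	2.3639	2.4016	-2.1149	-0.4696	0.5604	-1.5955	2.6609	-1.9759	-1.6070	1.3283	0.3535	1.5384	2.0047	-0.0829	0.4104	-0.8912	-1.9836	-0.8019
SYN047	-0.7697	-1.8003	0.5718	0.9463	-0.6222	-0.7293	0.1432	-0.6924	1.4183	-0.5739	-0.5990	0.6119	-0.1923	1.2376	1.6913	-0.2324	-0.3832	-0.9945	0.3395	0.6294
SYN048	-0.8927	0.2282	-1.3341	-1.3453	1.0512	-0.8718	0.5937	0.2233	-0.6071	0.5307	0.4680	0.3085	-0.4021	-0.2917	-0.3434	-0.5943	-0.1872	0.5560	1.2499	1.6602
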