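probe_id	S0000R1	S0001R1	S0002R1	S0003R1	S0004R1	S0005R1	S0006R1	S0007R1	S0008R1	S0009R1	S0010R1	S0011R1	S0000R2	S0001R2	S0002R2	S0003R2	S0004R2	S0005R2	S0006R2	S0007R2	S0008R2	S0009R2	S0010R2	S0011R2
cg00000000	0.72954	0.891739	0.522561	0.622882	0.999999	0.823104	0.999999	0.77939	0.33102	0.790645	0.559061	0.796076	0.835409	0.722737	0.580639	0.610823	0.999999	0.900122	0.999999	0.999999	0.432549	0.835286	0.687955	0.815104
cg00000001	0.987069	0.800076	0.578728	0.740424	0.628234	0.679487	0.491597	0.883189	0.427311	0.551214	0.999999	0.353491	0.732103	0.884993	0.343734	0.606889	0.751351	0.49732	0.56362	0.813357	0.418814	0.573732	0.999999	0.44633
cg00000002	0.029975	0.328454	0.210954	0.538882	0.375694	0.327001	0.367315	0.554059	0.349311	0.29263	0.440664	0.449836	0.137438	0.518949	0.177015	0.604674	0.264136	0.593778	0.546527	0.522399	0.357929	0.253951	0.39089	0.262474
cg00000003	NA	0.700509	0.748455	0.692309	0.542989	0.77899	0.495853	0.658253	0.479746	0.692846	0.642098	0.706619	0.672264	0.772549	0.434502	0.485017	0.544135	0.512025	0.587578	0.514203	0.738054	0.676263	0.34594	0.844302
cg00000004	0.390956	0.558236	0.538665	0.321684	0.283838	0.772968	0.456679	0.602471	0.56467	0.781403	0.23461	0.615146	0.424741	0.34803	0.588315	0.313188	0.443001	0.609869	0.585511	0.77702	0.478234	0.896907	0.383119	0.583319
cg00000005	0.778679	0.769289	0.999999	0.85232	0.795451	0.853289	0.362828	0.680814	0.490399	0.987427	0.667218	0.900018	0.817671	0.705119	0.898174	0.696617	0.849484	0.694083	0.570166	0.717314	0.999999	0.959702	0.618229	0.980303
cg00000006	0.363944	0.838971	0.424913	0.567452	0.765184	0.779812	0.551043	0.55482	0.88458	0.66976	0.39322	0.999999	0.331465	0.946217	0.597998	0.51566	0.870045	0.660674	0.386484	0.728292	0.999999	0.695243	0.53135	0.999999
cg00000007	0.426774	0.397834	0.293129	0.381864	0.397183	NA	0.390485	0.511481	0.491985	0.602804	0.538796	0.468771	0.50411	0.454504	0.325895	0.430791	0.377352	0.450766	0.395564	0.430809	0.452543	0.595893	0.596681	0.545092
cg00000008	0.321949	1e-06	0.113311	0.723964	0.717971	0.612787	0.412936	0.675312	0.806173	0.362693	0.69924	0.59143	0.392115	0.269884	1e-06	0.591406	0.758051	0.878948	0.210667	0.518915	0.520013	0.368475	0.722474	0.610957
cg00000009	0.53974	0.467689	0.545737	0.193936	1e-06	0.407098	0.137556	0.088139	0.391531	0.258417	0.387876	0.743434	0.453727	0.55378	0.525728	0.193292	1e-06	0.455395	0.12212	0.101298	0.389265	0.30949	0.389837	0.685551
cg00000010	0.57265	0.668311	0.795159	0.70238	0.975298	0.760717	0.627498	0.566761	0.878941	0.688082	0.546284	0.548015	0.827487	0.719596	0.830612	0.799536	0.955024	0.841147	0.817827	0.670152	0.965766	0.724875	0.552136	0.426156
cg00000011	0.585717	0.108301	0.406841	1e-06	0.019906	0.190997	0.030626	0.131057	0.476872	0.568415	0.80694	0.199211	0.207193	0.277201	0.422441	0.012922	1e-06	0.181715	0.191748	0.070028	0.570073	0.6735	0.985044	0.183276
cg00000012	0.889224	0.999999	0.836266	0.91211	0.792045	0.631798	0.661574	0.843323	0.746827	0.868518	0.673418	0.606351	0.781733	0.749395	0.628138	0.999999	0.951123	0.811034	0.716357	0.741443	0.825617	0.584863	0.748397	0.966601
cg00000013	0.324491	0.351801	0.50096	0.148949	0.321837	0.275043	0.248829	0.418458	0.026905	0.606235	0.257561	0.445259	0.303422	0.396679	0.413984	0.016592	0.46296	0.252824	0.20798	0.333201	0.065742	0.585554	0.207695	0.434966
cg00000014	0.464925	0.253962	0.509391	0.082651	0.237577	0.3752	0.602715	0.647877	0.614271	0.790662	0.526024	1e-06	0.472043	0.434728	0.563296	0.060704	0.244204	0.403431	0.606728	0.499736	0.433843	0.633861	0.346972	0.074921
cg00000015	0.241088	0.544751	0.692972	0.461186	0.382044	0.478384	0.245458	0.357428	0.59368	0.224727	0.311462	0.494554	0.239821	0.569243	0.662969	0.43287	0.368743	0.502003	0.322781	0.424018	0.490217	0.158834	0.379747	0.499872
cg00000016	1e-06	0.420555	0.057723	1e-06	0.01779	0.47659	0.780563	0.18163	1e-06	0.057669	0.067547	0.334015	1e-06	0.151918	0.030022	1e-06	1e-06	0.417913	0.630355	0.383053	0.06326	1e-06	0.235104	0.333412
cg00000017	0.836594	0.730705	0.740389	0.81641	0.999999	0.626764	0.802156	0.999999	0.674219	0.946443	0.999999	0.77654	0.949879	0.471737	0.749925	0.475048	0.988728	0.64481	0.961638	0.873289	0.575672	0.561294	0.313028	0.833326
cg00000018	0.581268	0.874919	0.86983	0.999999	0.92112	0.928675	0.999999	0.852689	0.993621	0.742667	0.700626	0.761218	0.563076	0.926575	0.882141	0.987291	0.920728	0.926092	0.999999	0.866124	0.997725	0.750852	0.724942	0.810627
cg00000019	0.457829	0.054082	0.601589	0.110727	0.388824	0.273609	0.808364	0.178277	0.076512	0.563907	0.143169	0.576368	0.54114	1e-06	0.567925	0.064519	0.383254	0.560213	0.999999	0.134322	0.103643	0.510181	0.305847	0.35949
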