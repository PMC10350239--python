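probe_id	n_pairs	icc	sigma_b2	sigma_w2	sd_diff	hola	micc	class_icc	class_micc	mean_beta	sd_beta
cg00000000	12	0.857469	0.031876	0.00452959	0.0951797	0.186552	0.670916	Excellent	Good	0.76111	0.184612
cg00000001	12	0.792362	0.0338482	0.00877204	0.132454	0.25961	0.532752	Excellent	Fair	0.656378	0.205395
cg00000002	12	0.633113	0.0150421	0.00900356	0.134191	0.263014	0.370099	Good	Poor	0.370622	0.135103
cg00000003	11	-0.124336	0	0.0189141	0.194495	0.381209	-0.505545	Poor	Poor	0.620239	0.154274
cg00000004	12	0.740608	0.022692	0.00830637	0.12889	0.252625	0.487983	Good	Fair	0.523024	0.185865
cg00000005	12	0.42189	0.01162	0.016854	0.183598	0.359851	0.0620389	Fair	Poor	0.776858	0.187858
cg00000006	12	0.859802	0.0410411	0.00646469	0.113707	0.222867	0.636936	Excellent	Good	0.669047	0.197178
cg00000007	11	0.820517	0.00630998	0.0013214	0.0514081	0.10076	0.719757	Excellent	Good	0.454831	0.0901361
cg00000008	12	0.786355	0.0504302	0.0148017	0.172056	0.33723	0.449124	Excellent	Fair	0.494986	0.238933
cg00000009	12	0.97782	0.0439429	0.00108612	0.0466072	0.0913502	0.88647	Excellent	Excellent	0.347527	0.205425
cg00000010	12	0.722413	0.0168986	0.00465804	0.0965198	0.189179	0.533234	Good	Fair	0.727517	0.154506
cg00000011	12	0.865617	0.0681955	0.0113123	0.150415	0.294813	0.570804	Excellent	Fair	0.304168	0.295305
cg00000012	12	-0.204218	0	0.0190057	0.194965	0.382131	-0.586349	Poor	Poor	0.790256	0.116159
cg00000013	12	0.901251	0.0233554	0.00256479	0.0716211	0.140377	0.760874	Excellent	Excellent	0.316997	0.148632
cg00000014	12	0.86186	0.0399639	0.00657328	0.114658	0.224731	0.63713	Excellent	Good	0.411655	0.20573
cg00000015	12	0.933834	0.0195171	0.00150651	0.0548911	0.107586	0.826247	Excellent	Excellent	0.419952	0.154054
cg00000016	12	0.86296	0.0459769	0.00788082	0.125545	0.246069	0.616891	Excellent	Good	0.193297	0.243875
cg00000017	12	0.0819721	0.00324301	0.0304991	0.246978	0.484077	-0.402105	Poor	Poor	0.764525	0.213321
cg00000018	12	0.984084	0.0170447	0.000237164	0.0217791	0.042687	0.941397	Excellent	Excellent	0.857617	0.131819
cg00000019	12	0.875369	0.0617751	0.00926005	0.136089	0.266734	0.608636	Excellent	Good	0.365158	0.236004
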