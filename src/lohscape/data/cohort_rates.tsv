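sample	group	sex	total_mb	freq_MM_pct	freq_mm_e2pct	freq_Mm_e2pct	r_MM_e3pct	r_goh_M_e3pct	r_mm_pct	r_goh_m_pct	r_Mm_pct	r_loh_pct	r_Mm_to_MM_pct	r_Mm_to_mm_pct	mm_ratio
Gastric 1	gastric	M	16.08	99.978	0.760	1.393	0.616	0.616	1.146	1.146	22.277	21.964	17.723	4.241	4.179
Gastric 2	gastric	M	24.50	99.952	2.105	2.698	0.531	0.531	0.737	0.717	0.544	0.423	0.287	0.136	2.111
Gastric 3	gastric	M	24.84	99.961	2.040	1.903	0.221	0.221	0.138	0.138	2.813	2.390	1.523	0.867	1.756
Gastric 4	gastric	M	18.22	99.969	1.327	1.798	0.297	0.297	0.414	0.414	2.809	2.565	1.924	0.641	3.000
Gastric 5	gastric	M	16.67	99.975	0.593	1.920	0.606	0.606	0.910	0.910	3.062	2.999	2.593	0.406	6.385
Glioma 1	glioma	F	18.92	99.964	1.236	2.381	0.169	0.169	0.086	0.086	1.421	1.421	1.043	0.377	2.765
Glioma 2	glioma	M	9.84	99.960	1.707	2.310	0.468	0.468	0.298	0.298	13.154	9.239	6.863	2.376	2.889
Glioma 3	glioma	M	21.08	99.959	1.973	2.118	3.166	3.071	4.257	3.920	24.009	22.307	16.484	5.823	2.831
Glioma 4	glioma	F	8.89	99.956	2.197	2.240	7.294	7.249	0.154	0.154	4.671	4.269	2.963	1.306	2.269
Glioma 5	glioma	M	10.49	99.964	1.776	1.866	4.749	4.702	10.574	9.662	26.622	26.162	21.564	4.599	4.689
Leukemia 1	leukemia	F	15.36	99.960	1.650	2.367	0.091	0.085	0.039	0.039	0.303	0.275	0.248	0.028	9.000
Leukemia 2	leukemia	F	13.00	99.956	1.824	2.604	0.085	0.085	0.000	0.000	0.296	0.266	0.207	0.059	3.500
Leukemia 3	leukemia	M	21.91	99.954	1.799	2.777	0.059	0.059	0.101	0.101	0.427	0.329	0.279	0.049	5.667
Leukemia 4	leukemia	F	17.75	99.975	0.712	1.773	0.118	0.118	0.238	0.238	1.208	1.017	0.890	0.127	7.000
Leukemia 5	leukemia	M	20.98	99.975	0.847	1.689	0.243	0.243	0.675	0.675	1.383	1.185	1.016	0.169	6.000
Liver 1	liver	F	10.85	99.980	0.780	1.237	3.881	3.844	10.520	10.284	27.103	26.731	23.083	3.649	6.327
Liver 2	liver	M	17.73	99.962	1.310	2.511	0.717	0.717	1.421	1.291	13.814	12.736	11.927	0.809	14.750
Liver 3	liver	M	12.04	99.955	1.926	2.574	0.590	0.590	0.862	0.862	6.387	5.226	4.323	0.903	4.786
Liver 4	liver	M	7.93	99.965	1.359	2.122	0.605	0.593	1.763	1.391	16.162	16.102	13.131	2.971	4.420
Liver 5	liver	M	11.08	99.957	1.984	2.274	0.352	0.352	0.227	0.227	7.302	6.587	5.357	1.230	4.355
Lung 1	lung	M	11.94	99.952	1.956	2.821	0.260	0.260	0.899	0.899	6.980	6.920	5.495	1.426	3.854
Lung 2	lung	M	12.96	99.956	2.400	1.963	2.454	2.454	1.479	1.318	11.635	11.439	10.653	0.786	13.553
Lung 3	lung	F	14.23	99.964	1.368	2.207	1.680	1.673	3.236	3.236	7.291	6.495	5.858	0.637	9.200
Lung 4	lung	M	12.49	99.965	1.286	2.234	2.811	2.811	6.476	6.413	5.661	5.410	5.016	0.394	12.727
Lung 5	lung	F	14.46	99.950	2.057	2.896	11.609	10.633	20.134	15.261	49.690	48.161	37.751	10.411	3.626
Lung-Brain 1	lung_brain	M	21.69	99.934	2.688	3.884	0.807	0.807	0.583	0.566	2.125	1.840	1.425	0.416	3.429
Lung-Brain 2	lung_brain	M	21.68	99.943	2.432	3.208	0.858	0.844	0.512	0.493	7.346	6.627	4.572	2.056	2.224
Lung-Brain 3	lung_brain	F	17.04	99.948	1.894	3.302	0.564	0.564	1.209	1.178	1.707	1.120	1.013	0.107	9.500
Lung-Brain 4	lung_brain	M	22.79	99.948	1.886	3.292	0.931	0.917	1.024	1.024	5.052	4.679	3.332	1.346	2.475
Lung-Brain 5	lung_brain	M	21.04	99.937	2.708	3.625	0.528	0.528	0.158	0.140	1.285	0.931	0.695	0.236	2.944
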