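analysis	dataset	h2	se	n_snp
unweighted_t5	module_1	0.069	0.016	183
unweighted_t5	module_2	0.062	0.015	204
unweighted_t5	module_3	0.061	0.016	145
unweighted_t5	module_4	0.088	0.018	944
unweighted_t5	module_5	0.088	0.018	536
unweighted_t5	module_6	0.040	0.012	192
unweighted_t5	module_7	0.045	0.013	101
unweighted_t5	module_8	0.081	0.017	528
unweighted_t5	module_9	0.081	0.017	624
unweighted_t5	module_10	0.015	0.014	296
weighted_t5	module_1	0.106	0.049	183
weighted_t5	module_2	0.099	0.050	204
weighted_t5	module_3	0.094	0.053	145
weighted_t5	module_4	0.137	0.0374	944
weighted_t5	module_5	0.156	0.026	536
weighted_t5	module_6	0.073	0.072	192
weighted_t5	module_7	0.081	0.066	101
weighted_t5	module_8	0.131	0.036	528
weighted_t5	module_9	0.128	0.040	624
weighted_t5	module_10	0.089	0.061	296
weighted_all	pedigree_unweighted	0.366	0.045	49691
weighted_all	genomic_unweighted	0.269	0.031	49691
weighted_all	module_1	0.270	0.035	49691
weighted_all	module_2	0.271	0.037	49691
weighted_all	module_3	0.269	0.028	49691
weighted_all	module_4	0.273	0.040	49691
weighted_all	module_5	0.272	0.038	49691
weighted_all	module_6	0.270	0.034	49691
weighted_all	module_7	0.269	0.026	49691
weighted_all	module_8	0.272	0.039	49691
weighted_all	module_9	0.273	0.039	49691
weighted_all	module_10	0.270	0.035	49691
unweighted_t2	module_1	0.209	0.028	5915
unweighted_t2	module_2	0.182	0.026	5259
unweighted_t2	module_3	0.139	0.022	1992
unweighted_t2	module_4	0.221	0.027	7290
unweighted_t2	module_5	0.184	0.025	4442
unweighted_t2	module_6	0.175	0.025	4311
unweighted_t2	module_7	0.148	0.022	1951
unweighted_t2	module_8	0.229	0.028	9283
unweighted_t2	module_9	0.225	0.028	7932
unweighted_t2	module_10	0.183	0.025	4250
weighted_t2	module_1	0.217	0.036	5915
weighted_t2	module_2	0.205	0.035	5259
weighted_t2	module_3	0.166	0.043	1992
weighted_t2	module_4	0.255	0.026	7290
weighted_t2	module_5	0.222	0.028	4442
weighted_t2	module_6	0.200	0.037	4311
weighted_t2	module_7	0.174	0.041	1951
weighted_t2	module_8	0.250	0.030	9283
weighted_t2	module_9	0.238	0.031	7932
weighted_t2	module_10	0.208	0.034	4250
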