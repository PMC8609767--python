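sample	array_purity	array_loh	array_tai	array_lst	array_ploidy	array_hrd_score	panel_purity	panel_loh	panel_tai	panel_lst	panel_ploidy	panel_hrd_score
S001	0.4	30	17	62	2.57	69.11	0.44	34	18	80	3.31	80.64
S002	0.38	32	18	55	2.39	67.98	0.41	29	18	63	2.66	68.75
S003	0.64	27	20	36	1.84	54.55	0.75	31	20	42	1.95	62.77
S004	0.6	32	18	40	1.85	61.33	0.69	33	18	41	1.92	62.23
S005	0.68	22	19	67	3.17	58.81	0.79	22	19	71	3.23	61.88
S006	0.48	20	17	74	3.19	61.6	0.53	19	19	76	3.64	57.53
S007	0.46	25	18	27	1.64	44.58	0.41	28	21	36	1.94	54.99
S008	0.59	26	20	30	1.75	48.87	0.7	28	21	32	1.78	53.39
S009	0.5	7	14	87	3.44	54.73	0.51	9	19	78	3.7	48.59
S010	0.21	30	14	32	2.0	44.98	0.31	24	19	34	1.99	46.11
S011	0.52	24	15	30	1.75	41.88	0.62	24	12	39	1.91	45.41
S012	0.58	20	15	29	1.81	35.92	0.64	21	16	36	1.94	42.91
S013	0.39	23	18	48	3.23	38.94	0.45	22	22	48	3.28	41.22
S014	0.43	15	22	54	2.82	47.34	0.53	13	16	60	3.12	40.6
S015	0.61	21	16	31	1.66	42.25	0.72	23	14	32	1.87	40.03
S016	0.35	23	13	37	2.52	33.98	0.46	17	9	62	3.14	39.36
S017	0.72	19	15	26	1.76	32.74	0.83	20	16	32	1.88	38.92
S018	0.5	17	16	55	3.59	32.43	0.55	18	20	55	3.59	37.39
S019	0.3	24	19	38	2.96	35.19	0.37	23	18	43	3.04	36.91
S020	0.6	19	14	27	1.92	30.23	0.67	19	16	29	2.03	32.58
S021	0.62	12	17	48	3.33	25.35	0.7	14	18	53	3.39	32.5
S022	0.55	15	12	53	3.68	22.97	0.67	17	14	55	3.71	28.52
S023	0.28	20	13	30	2.13	30.03	0.26	17	15	37	2.61	28.49
S024	0.59	16	13	25	1.82	25.83	0.66	17	17	26	1.92	30.24
S025	0.54	16	14	24	1.78	26.36	0.58	16	14	24	1.81	25.96
S026	0.34	7	13	47	3.58	11.49	0.43	7	18	57	3.66	25.21
S027	0.77	18	11	25	1.85	25.35	0.88	15	19	29	2.01	31.84
S028	0.72	18	13	26	1.85	28.38	0.83	16	11	26	1.94	22.99
S029	0.25	14	7	18	2.04	7.34	0.21	17	9	37	2.65	21.96
S030	0.73	17	12	21	1.89	20.69	0.83	17	12	23	1.94	21.96
S031	0.67	18	13	23	1.87	24.95	0.79	18	11	23	1.94	21.94
S032	0.61	17	8	23	1.95	17.77	0.68	18	8	25	2.01	19.83
S033	0.49	15	11	30	2.81	12.47	0.67	18	11	35	2.92	18.67
S034	0.56	18	9	18	1.68	18.9	0.65	15	7	21	1.69	16.83
S035	0.36	12	8	16	1.83	7.59	0.39	13	9	24	2.06	14.11
S036	0.7	8	13	32	2.76	10.16	0.77	6	15	35	2.84	12.04
S037	0.72	8	3	5	1.89	-13.35	0.83	5	2	6	1.91	-16.63
S038	0.41	5	4	8	2.02	-14.37	0.43	4	2	10	2.12	-16.87
S039	0.34	1	1	1	1.98	-27.67	0.34	2	1	8	2.33	-25.12
S040	1.0	0	0	0	2.0	-31.0	1.0	0	0	0	2.0	-31.0
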