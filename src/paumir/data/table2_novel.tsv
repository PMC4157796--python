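mirna	pa2	pa4	printed_fc	printed_p	star_pa2	star_pa4
pas-mir1	116	422	1.86	7.02E-42	106	74
pas-mir2	43	0	-8.65	1.09E-13	0	0
pas-mir3	8	3	-1.42	1.45E-01	6	5
pas-mir4a	6	0	-5.81	1.55E-02	0	0
pas-mir4b	6	0	-5.81	1.55E-02	0	0
pas-mir5a	7116	6078	-0.23	5.38E-20	208	223
pas-mir5b	7116	6078	-0.23	5.38E-20	208	223
pas-mir6a-3p	2125	4098	0.94	1.51E-139	67	71
pas-mir6b-3p	2125	4098	0.94	1.51E-139	67	71
pas-mir6c-3p	2125	4098	0.94	1.51E-139	67	71
pas-mir7-3p	696	0	-12.67	1.51E-210	6	0
pas-mir8a-3p	29	0	-8.08	4.57E-01	0	0
pas-mir8b-3p	29	11	-1.4	5.48E-02	0	0
pas-mir9	8	0	-6.23	3.87E-03	0	0
pas-mir10-3p	10	0	-6.55	9.66E-04	0	0
pas-mir11-3p	17	0	-7.31	7.49E-06	0	0
pas-mir12	5	0	-5.55	3.11E-02	0	0
pas-mir13-3p	934	1506	0.69	5.10E-31	1128	1403
pas-mir14	10	28	1.48	3.45E-03	2	1
pas-mir15a	345	0	-11.66	9.86E-105	107	0
pas-mir16a-3p	0	19	7.47	1.95E-06	0	0
pas-mir16b-3p	0	19	7.47	1.95E-06	0	0
pas-mir16c-3p	0	19	7.47	1.95E-06	0	0
pas-mir17-3p	0	8	6.22	3.94E-03	0	7
pas-mir18-3p	0	11	6.68	4.94E-04	0	0
pas-mir19-3p	0	126	10.2	1.34E-38	0	0
pas-mir20-3p	0	54	8.98	5.87E-17	0	2
pas-mir21a	0	12	6.81	2.47E-04	0	9
pas-mir21b	0	12	6.81	2.47E-04	0	9
pas-mir22-3p	0	11	6.68	4.94E-04	0	0
pas-mir23-3p	0	28	8.03	3.84E-09	0	0
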