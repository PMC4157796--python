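family	mirna	pa2	pa4	printed_fc	printed_p	star_pa2	star_pa4
MIR169	pas-miR169a-3p	252	142	-0.83	2.27E-08	180	87
MIR169	pas-miR169b-3p	244	0	-11.16	2.77E-74	173	0
MIR169	pas-miR169c-3p	244	0	-11.16	2.77E-74	173	0
MIR169	pas-miR169d	18	26	0.53	2.35E-01	0	0
MIR169	pas-miR169e	18	26	0.53	2.35E-01	0	0
MIR159	pas-miR159-3p	117706	141387	0.26	0	115	83
MIR159	pas-miR319a-3p	1312	85	-3.95	0	16	0
MIR408	pas-miR408a-3p	1475	6263	2.08	0	50	208
MIR408	pas-miR408b-3p	1475	6263	2.08	0	50	208
MIR396	pas-miR396a	7879	6831	-0.21	1.86E-18	142	153
MIR396	pas-miR396b	2808	3441	0.29	2.11E-15	120	263
MIR396	pas-miR396c-3p	0	30	8.13	9.61E-10	13	11
MIR396	pas-miR396d-3p	0	30	8.13	9.61E-10	13	11
MIR397	pas-miR397a	676	6543	3.27	0	16	368
MIR397	pas-miR397b	678	6601	3.28	0	16	368
MIR398	pas-miR398a-3p	532	3071	2.53	0	44	1042
MIR398	pas-miR398b-3p	532	3071	2.53	0	44	1042
MIR398	pas-miR398c-3p	532	3071	2.53	0	44	1042
MIR166	pas-miR166a-3p	178621	189900	0.09	3.20E-72	1809	1883
MIR166	pas-miR166b-3p	180817	192950	0.09	1.90E-82	141	332
MIR166	pas-miR166c-3p	550961	563946	0.03	2.62E-29	1689	1755
MIR166	pas-miR166d-3p	422623	424471	0.00	2.78E-01	373	236
MIR166	pas-miR166e-3p	50932	51265	0.01	4.71E-01	490	455
MIR160	pas-miR160a	718	1445	1.01	8.76E-56	0	1
MIR160	pas-miR160b	30	40	0.41	2.38E-01	0	0
MIR160	pas-miR160c	30	40	0.41	2.38E-01	0	0
MIR160	pas-miR160d	30	40	0.41	2.38E-01	0	0
MIR160	pas-miR160e	30	40	0.41	2.38E-01	0	0
MIR160	pas-miR160f	30	40	0.41	2.38E-01	0	0
MIR156	pas-miR156a	2251	3231	0.51	5.59E-39	0	0
MIR156	pas-miR156b	2251	3221	0.51	4.75E-39	46	69
MIR156	pas-miR156c	1349	2284	0.76	1.94E-54	278	493
MIR156	pas-miR156d	1349	2284	0.76	1.94E-54	278	493
MIR164	pas-miR164	396	284	-0.48	1.51E-05	85	40
MIR167	pas-miR167	509	864	0.76	8.46E-22	18	27
MIR168	pas-miR168a	1893	2713	0.52	2.06E-33	143	236
MIR168	pas-miR168b	1895	2712	0.51	3.58E-33	137	185
MIR2118	pas-miR2118a-3p	109	136	0.32	8.78E-02	0	0
MIR2118	pas-miR2118b-3p	109	136	0.32	8.78E-02	0	0
MIR482	pas-miR482a-3p	4727	6806	0.52	5.00E-83	0	0
MIR482	pas-miR482b-3p	4529	4723	0.06	5.48E-02	0	0
MIR482	pas-miR482c-3p	4728	6804	0.52	8.48E-83	0	0
MIR171	pas-miR171a	0	10	6.54	9.87E-04	0	0
MIR171	pas-miR171b	0	8	6.22	3.94E-03	0	0
MIR171	pas-miR171c	0	8	6.22	3.94E-03	0	0
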