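label	hemisphere	x_mni_mm	y_mni_mm	z_mni_mm	radius_mm	peak_z
L. Superior frontal gyrus (dorsal)	L	-10	66	26	5	6.46
L. Superior frontal gyrus (medial)	L	0	68	2	5	6.54
R. Superior frontal gyrus (medial)	R	4	64	0	5	6.35
L. Orbitofrontal gyrus (superior)	L	-8	68	-8	5	5.7
L. Middle frontal gyrus	L	-30	28	46	5	5.84
L. Orbitofrontal gyrus (middle)	L	-28	36	-14	5	5.95
L. Orbitofrontal gyrus (medial)	L	0	68	-4	5	7.37
R. Orbitofrontal gyrus (medial)	R	4	64	-6	5	7.73
L. Orbitofrontal gyrus (inferior)	L	-28	34	-14	5	5.7
L. Rectus gyrus	L	-4	52	-16	5	6.35
R. Rectus gyrus	R	4	42	-16	5	6.64
L. Precentral gyrus	L	-56	-6	30	5	7.24
R. Precentral gyrus	R	36	-20	44	5	7.68
L. Paracentral lobule	L	-12	-34	50	5	5.55
R. Paracentral lobule	R	12	-40	52	5	6.39
R. Supplementary motor area	R	44	51	67	5	5.85
L. Postcentral gyrus	L	-54	-8	26	5	7.34
R. Postcentral gyrus	R	54	-12	36	5	7.68
L. Anterior cingulate gyrus	L	-2	38	-8	5	6.63
R. Anterior cingulate gyrus	R	4	34	-6	5	6.01
L. Middle cingulate gyrus	L	-8	-44	48	5	7.95
R. Middle cingulate gyrus	R	8	-42	50	5	6.32
L. Posterior cingulate gyrus	L	-8	-48	32	5	7.16
L. Superior parietal gyrus	L	-16	-56	52	5	6.15
R. Superior parietal gyrus	R	16	-50	56	5	6.25
L. Inferior parietal gyrus	L	-36	-78	42	5	5.96
L. Precuneus	L	-10	-44	48	5	8.15
R. Precuneus	R	2	-50	52	5	7.88
L. Angular gyrus	L	-40	-74	40	5	6.32
L. Supramarginal gyrus	L	-64	-32	32	5	5.02
R. Supramarginal gyrus	R	48	-16	30	5	6.44
L. Superior temporal gyrus	L	-58	-2	-14	5	5.62
R. Superior temporal gyrus	R	62	-8	2	5	7.13
L. Middle temporal gyrus	L	-58	-4	-18	5	7.34
R. Middle temporal gyrus	R	58	-6	-14	5	5.8
L. Inferior temporal gyrus	L	-54	-4	-28	5	6.46
R. Inferior temporal gyrus	R	54	60	22	5	5.2
L. Temporal pole (superior)	L	-54	6	-16	5	4.98
R. Temporal pole (superior)	R	62	2	0	5	5.78
L. Temporal pole (middle)	L	-58	-4	-18	5	4.84
R. Temporal pole (middle)	R	28	12	-36	5	5.33
L. Heschl's gyrus	L	-34	-24	14	5	4.56
R. Heschl's gyrus	R	36	-26	16	5	6.83
L. Fusiform gyrus	L	-28	-50	-12	5	7.56
R. Fusiform gyrus	R	24	-64	-8	5	7.72
L. Superior occipital gyrus	L	-16	-94	20	5	8.38
R. Superior occipital gyrus	R	18	-90	26	5	7.32
L. Middle occipital gyrus	L	-18	-90	18	5	7.11
R. Middle occipital gyrus	R	26	-88	20	5	8.32
L. Lingual gyrus	L	-20	-66	-12	5	7.56
R. Lingual gyrus	R	24	-52	-10	5	8.01
L. Calcarine cortex	L	-10	-60	6	5	7.96
R. Calcarine cortex	R	8	-90	12	5	7.73
L. Cuneus	L	-8	-74	18	5	7.93
R. Cuneus	R	10	-92	16	5	7.52
L. Parahippocampal cortex	L	-12	-34	50	5	5.55
R. Parahippocampal cortex	R	12	-40	52	5	6.39
L. Insula	L	-36	-16	16	5	5.43
R. Insula	R	34	-14	6	5	6.39
L. Rolandic operculum	L	-38	-16	18	5	5.47
R. Rolandic operculum	R	66	-6	8	5	6.91
R. Putamen	R	34	-14	2	5	6.16
R. Pallidum	R	28	-12	-2	5	5.37
L. Thalamus	L	-16	-26	0	5	5.01
R. Thalamus	R	16	-26	0	5	4.05
L. Amygdala	L	-20	-6	-18	5	3.64
L. Hippocampus	L	-22	-14	-24	5	5.25
R. Hippocampus	R	24	-12	-22	5	5.93
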