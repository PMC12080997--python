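region	hemisphere	volume_mm3	position	abbreviation
Nucleus Accumbens	left	7.944	1	NAc
Nucleus Accumbens	right	7.944	2	NAc
Amygdala	left	21.120	3	Amyg
Amygdala	right	21.120	4	Amyg
Dorsal Striatum	left	43.552	5	Str
Dorsal Striatum	right	43.552	6	Str
Auditory Cortex	left	27.520	7	Au
Auditory Cortex	right	27.520	8	Au
Cingulate Cortex	left	14.480	9	Cg
Cingulate Cortex	right	14.480	10	Cg
Entorhinal Cortex	left	59.016	11	Ent
Entorhinal Cortex	right	59.016	12	Ent
Insular Cortex	left	21.128	13	Ins
Insular Cortex	right	21.128	14	Ins
Medial Prefrontal Cortex	left	6.304	15	mPFC
Medial Prefrontal Cortex	right	6.304	16	mPFC
Motor Cortex	left	32.608	17	M1
Motor Cortex	right	32.608	18	M1
Orbitofrontal Cortex	left	18.936	19	OFC
Orbitofrontal Cortex	right	18.936	20	OFC
Parietal Cortex	left	7.632	21	PaC
Parietal Cortex	right	7.632	22	PaC
Retrosplenial Cortex	left	18.920	23	RS
Retrosplenial Cortex	right	18.920	24	RS
Somatosensory Cortex	left	71.600	25	S1
Somatosensory Cortex	right	71.600	26	S1
Visual Cortex	left	36.136	27	V1
Visual Cortex	right	36.136	28	V1
Anterodorsal Hippocampus	left	25.064	29	CA1
Anterodorsal Hippocampus	right	25.064	30	CA1
Posterior Hippocampus	left	9.784	31	CA1-p
Posterior Hippocampus	right	9.784	32	CA1-p
Hypothalamus	left	18.352	33	Hyp
Hypothalamus	right	18.352	34	Hyp
Olfactory Cortex	left	14.008	35	OC
Olfactory Cortex	right	14.008	36	OC
Superior Colliculus	left	7.136	37	SC
Superior Colliculus	right	7.136	38	SC
Midbrain	left	11.448	39	MB
Midbrain	right	11.448	40	MB
Ventral Tegmental Area	left	5.528	41	VTA
Ventral Tegmental Area	right	5.528	42	VTA
Inferior Colliculus	left	5.744	43	IC
Inferior Colliculus	right	5.744	44	IC
Thalamus	left	30.712	45	Th
Thalamus	right	30.712	46	Th
Periaqueductal Gray	midline	9.904	47	PAG
Septum	midline	9.360	48	Sep
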