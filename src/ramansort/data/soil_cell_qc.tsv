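# Marker-gene completeness and GC of draft genomes recovered from
# individually sorted soil cells: seven sorted on the C-D (heavy-water
# labeling) band and seven sorted on carotenoid resonance bands.
group	sample_id	genus	completeness_pct	genome_recovered_kbp	gc_pct
cd_peak	SR5	Corynebacterium	89.05	3003.41	60.12
cd_peak	SR6	Clostridium	22.25	1272.90	30.05
cd_peak	SR9	Moraxella	92.62	4772.96	43.21
cd_peak	BSR2	Pantoea	46.90	2397.74	54.60
cd_peak	BSR3	Pseudomonas	11.68	863.39	62.17
cd_peak	BSR5	Pantoea	23.43	1303.76	55.61
cd_peak	BSR11	Moraxella	90.23	2465.43	43.60
carotenoid	CRG1	Pantoea	58.66	3419.94	52.55
carotenoid	CRG2	Legionella	34.99	960.72	39.05
carotenoid	CRG4	Legionella	48.39	1202.08	37.93
carotenoid	CRG5	Legionella	12.23	143.52	38.89
carotenoid	CRG6	Massilia	19.44	605.58	62.84
carotenoid	CRG7	Pseudomonas	20.85	1698.06	58.72
carotenoid	CRG11	Pedobacter	13.01	43.11	41.25
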