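# Synthetic demonstration collagen marker table.
# Peptides are invented collagen-like sequences for testing the matching
# machinery; they are NOT published species marker masses.
species	marker_id	diagnostic	peptide	mass	max_hydroxylations
sheep_like	COL1-S1	1	GPPGEAGKPGEQGVPGDLGAPGPSGAR		2
sheep_like	COL1-S2	1	GETGPAGPAGPIGPVGAR		1
sheep_like	COL1-S3	1	GSAGPPGATGFPGAAGR		2
goat_like	COL1-G1	1	GPPGEAGKPGEQGVPGDLGAPGPSGAR		2
goat_like	COL1-G2	1	GETGPAGPAGPVGPVGAR		1
goat_like	COL1-G3	1	GSNGEPGSAGPPGPAGLR		1
cow_like	COL1-C1	1	GPSGEPGKQGPSGASGER		1
cow_like	COL1-C2	1	GLTGSPGSPGPDGK		1
cow_like	COL1-C3	1	GSAGPPGATGFPGAAGR		2
human_like	COL1-H1	1	GVQGPPGPAGPR		1
human_like	COL1-H2	1	GESGPSGPAGPTGAR		1
human_like	COL1-H3	1	GANGAPGIAGAPGFPGAR		1
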