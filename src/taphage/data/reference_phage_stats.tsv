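# Published ACA-site statistics for the 12 NCBI reference (+)ssRNA phage genomes
# (accessions from the NCBI Viral Genomes Database). shuffle_percent_higher is the
# reported percentage of 10,000 composition-preserving shuffles with more ACA sites
# than the original genome.
accession	phage_name	species	pilus_group	host	moltype	genome_length	aca_observed	aca_expected_rounded	aca_relative_frequency	shuffle_percent_higher
NC_001417.2	MS2	Emesvirus zinderi	F plasmid-specific Group I	Escherichia	ssRNA+	3569	47	51	0.92	69.75
NC_001426.1	BZ13	Emesvirus japonicum	Group II	Escherichia	ssRNA+	3466	32	50	0.64	99.75
NC_001890.1	Qbeta	Qubevirus durum	Group III	Escherichia	ssRNA+	4215	53	59	0.90	76.03
NC_028902.1	FI-4184b	Qubevirus faecium	Group IV	Escherichia	ssRNA+	4184	44	56	0.78	95.52
NC_004301.1	FI-SP	Qubevirus faecium	Group IV	Escherichia	ssRNA+	4276	47	62	0.76	97.43
NC_019920.1	C-1	Cunavirus pretoriense	IncC-specific	Escherichia	ssRNA+	3523	35	52	0.68	99.50
NC_019922.1	Hgal1	Hagavirus psychrophilum	IncH-specific	Escherichia	ssRNA+	3562	32	54	0.59	99.94
NC_019707.1	M	Empivirus allolyticum	IncM-specific	Escherichia	ssRNA+	3405	42	47	0.89	76.65
NC_008294.1	PRR1	Perrunavirus olsenii	IncP-specific	Escherichia; Pseudomonas	ssRNA+	3573	38	54	0.70	98.70
NC_001628.1	PP7	Pepevirus rubrum	plasmid-independent	Pseudomonas	ssRNA+	3588	38	45	0.85	82.92
NC_019453.1	phiCb5	Cebevirus halophobicum	plasmid-independent	Caulobacter	ssRNA+	3762	32	52	0.62	99.92
NC_002700.2	AP205	Apeevirus quebecense	plasmid-independent	Acinetobacter	ssRNA+	4268	71	68	1.04	32.82
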