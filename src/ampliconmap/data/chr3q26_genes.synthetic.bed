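# Synthetic gene annotation for the chr3q26.33 amplicon neighborhood.
# Nine RefSeq genes fall inside the 181.9-184.6 Mb listing interval, laid
# out in documented genomic order; coordinates are approximations, not a
# genome-build export. Flanking genes outside the interval are included so
# region queries are non-trivial.
chr3	180350000	180440000	PIK3CA
chr3	181950000	182010000	FXR1
chr3	182200000	182210000	DNAJC19
chr3	182600000	183350000	SOX2OT
chr3	182910000	182915000	SOX2
chr3	183500000	183630000	ATP11B
chr3	183800000	183840000	DCUN1D1
chr3	184000000	184100000	MCCC1
chr3	184250000	184290000	LAMP3
chr3	184450000	184470000	B3GNT5
chr3	184800000	184900000	KCNMB3
chr3	186500000	186520000	EIF4G1
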