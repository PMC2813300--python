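# Synthetic five-tumor 3q26.33 amplicon segments (BED4, name = tumor id).
# Each tumor's amplicon contains the 181.9-184.6 Mb consensus with
# differing outer limits; the strict intersection is 2.7 Mb wide.
chr3	179900000	185900000	T15
chr3	181900000	184600000	T35
chr3	181000000	185000000	T03
chr3	181500000	186000000	T11
chr3	180500000	185500000	T22
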