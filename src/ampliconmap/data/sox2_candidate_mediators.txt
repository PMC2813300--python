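# Literature-curated 16-entry list of cancer-related candidate mediator
# genes downstream of SOX2 in lung squamous cell carcinoma. One entry is a
# composite two-gene probe annotation kept verbatim. This list is static
# curation, excluded from all computed statistics.
CBX5
GATA3
MYCL1
HOXB7
HOXC4 /// HOXC6
RIT1
IGFBP5
NRG1
FGFBP1
FHL1
PTGIS
CASP1
CASP4
CLU
TGFBR3
TNFSF10
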