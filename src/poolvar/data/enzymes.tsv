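# Restriction enzymes used in the CAPS validation assays.
name	site
NotI	GCGGCCGC
TaqI	TCGA
MboI	GATC
MnlI	CCTC
FokI	GGATG
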