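gene_symbol	gene_name	adjusted_p
Cartpt	Cocaine and Amphetamine Regulated Transcript Prepropeptide	0.0000
Prdm8	PR/SET Domain 8	0.0000
RT1-A3	RT1 class I, locus A3 (also MHC class I protein)	0.0003
Hbs1l	Hsp70 Subfamily B Suppressor 1-Like Protein	0.0101
Pdyn	Prodynorphin	0.0403
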