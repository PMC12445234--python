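gene_symbol	gene_name	adjusted_p
CTTN	Cortactin	0.0000
Mras	Muscle RAS Oncogene Homolog	0.0000
Megf8	Multiple EGF Like Domains 8	0.0000
ATN1	Atrophin 1	0.0000
Rnf112	Ring Finger Protein 112 (also Zinc Finger Protein 179 (ZNF179))	0.0000
FAAH	Fatty Acid Amide Hydrolase	0.0000
Spock3	SPARC/Osteonectin, Cwcv and Kazal-Like Domains Proteoglycan 3	0.0000
Rpl19	Ribosomal protein L9-like	0.0001
Pnkd	Paroxysmal Nonkinesiogenic Dyskinesia (PNKD) Metallo-Beta-Lactamase Domain Containing	0.0002
Tcp11l1	T-Complex 11 Like 1	0.0002
Tbx19	T-box Transcription Factor 19	0.0007
Bcor	BCL6 Corepressor	0.0017
Slitrk5	SLIT and NTRK Like Family Member 5	0.0021
Rps28	Ribosomal Protein S28	0.0022
Socs5	Suppressor Of Cytokine Signaling 5	0.0028
Rps18	Ribosomal Protein S18	0.0039
Slc25a23	Solute Carrier Family 25 Member 23	0.0052
Dnal4	Dynein Axonemal Light Chain 4	0.0061
UBALD1	UBA Like Domain Containing 1	0.0111
Hmgb3	High Mobility Group Box 3	0.0120
Rps20	Ribosomal Protein S20	0.0169
Tecpr2	Tectonin Beta-Propeller Repeat-Containing 2	0.0213
Unknown	NA	0.0223
Nipsnap3b	Nipsnap Homolog 3B	0.0280
Nsg2	Neuronal Vesicle Trafficking Associated 2	0.0390
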