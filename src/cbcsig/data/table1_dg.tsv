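gene_symbol	gene_name	adjusted_p
RGD1563072	Similar to hypothetical protein FLJ38984	0.0000
CTTN	Cortactin	0.0000
Ywhaq	Tyrosine 3-Monooxygenase/Tryptophan 5-Monooxygenase Activation Protein Theta (also 14-3-3 protein theta)	0.0000
Rtn3	Reticulon 3	0.0000
Cartpt	Cocaine and Amphetamine Regulated Transcript Prepropeptide	0.0000
UBALD1	UBA Like Domain Containing 1	0.0000
ATN1	Atrophin 1	0.0000
Sept5	Septin 5	0.0000
Mfge8	Milk Fat Globule-EGF Factor-8	0.0000
TSEN34	tRNA-Splicing Endonuclease Subunit 34	0.0000
Rnf112	Ring Finger Protein 112 (also Zinc Finger Protein 179 (ZNF179))	0.0000
Mical2	Microtubule Associated Monooxygenase, Calponin And LIM Domain Containing 2	0.0000
Mfsd6	Major Facilitator Superfamily Domain Containing 6	0.0000
Rnf14	E3 Ubiquitin-protein Ligase Ring Finger Protein 14	0.0001
PEX12	Peroxisomal Biogenesis Factor 12	0.0001
Tnk2	Tyrosine Kinase Non Receptor 2 (also Activated Cdc42-associated kinase 1 (ACK1))	0.0001
Hspa4l	Heat Shock Protein Family A (Hsp70) Member 4 Like	0.0003
Nr1d1	Nuclear Receptor Subfamily 1 Group D Member 1	0.0003
Rpl19	Ribosomal Protein L19	0.0007
Rxfp1	Relaxin Family Peptide Receptor 1	0.0007
Snap25	Synaptosomal-Associated Protein, 25 kDa	0.0017
Mtpn	Myotrophin	0.0029
Abcd2	ATP-binding Cassette Sub-family D Member 2	0.0051
Rfk	Riboflavin Kinase	0.0052
Galnt18	Polypeptide N-Acetylgalactosaminyltransferase 18	0.0080
Tbx19	T-box Transcription Factor 19	0.0083
Atp2c1	ATPase Secretory Pathway Ca2+ Transporting 1	0.0108
Ywhab	Tyrosine 3-Monooxygenase/Tryptophan 5-Monooxygenase Activation Protein Beta (also 14-3-3 protein beta)	0.0112
Rab6a	RAB6A, member RAS oncogene family	0.0123
KPTN	Kaptin, Actin binding protein	0.0150
Wdr47	WD Repeat Domain 47	0.0151
Rtn4	Reticulon 4 (also Neurite Outgrowth Inhibitor (Nogo))	0.0181
Oxr1	Oxidation Resistance Protein 1	0.0186
Dpysl5	Dihydropyrimidinase Like 5 (also Collapsin Response Mediator Protein 5 (CRMP5))	0.0226
Uba3	Ubiquitin Like Modifier Activating Enzyme 3	0.0248
HAUS1	HAUS Augmin Like Complex Subunit 1	0.0333
Mast2	Microtubule Associated Serine/Threonine Kinase 2	0.0359
Pfdn6	Prefoldin Subunit 6	0.0394
Slc2a1	Solute Carrier Family 2 Member 1 (also Glucose transporter 1, GLUT1)	0.0404
Zmat3	Zinc Finger Matrin-Type 3 (also Wild Type p53-induced Gene 1 (Wig-1))	0.0411
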