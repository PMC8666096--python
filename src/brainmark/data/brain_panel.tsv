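accession	protein_name	cellular_component	avg_sc	log_e
Q92686	Neurogranin	Membrane; Cytoplasm	15	-6.40
Q96KN2	Beta-Ala-His dipeptidase	Secreted	7.25	-25.08
Q99884	Sodium-dependent proline transporter	Membrane	6	-2
P01213	Beta-neoendorphin-dynorphin	Secreted	2	-9.9
P56975	Pro-neuregulin-3, membrane-bound isoform	Membrane	2	-1.10
P14136	Glial fibrillary acidic protein	Cytoplasm	2	-6.33
O94933	SLIT and NTRK-like protein 3	Membrane	2	-5.3
P08908	5-hydroxytryptamine receptor 1A	Membrane	1	-1.1
A7E2E4	Dipeptidyl-peptidase 6	Membrane	1	-1.1
Q96FT7	Amiloride-sensitive cation channel 4	Membrane	1	-1.2
B3KXG7	Protein tyrosine phosphatase, non-receptor type 5	Endoplasmic reticulum membrane	1	-1.5
Q9P218	Collagen alpha-1(XX)	Secreted	1	-1.5
O95741	Copine-6	Mitochondrion	1	-1.2
Q9UI47	Catenin alpha-3	Cytoplasm	1	-1.3
P51674	Neuronal membrane glycoprotein M6-a	Membrane	1	-1.4
Q9UQM7	Calcium/calmodulin-dependent protein kinase type II subunit alpha	Membrane	1	-1.2
Q96NJ5	Kelch-like protein 32	Unknown	1	-2
Q8N967; Q6ZUR1	Leucine-rich repeat and transmembrane domain-containing protein 2	Membrane	1	-1.4
Q96NK8	Neurogenic differentiation factor 6	Nucleus	1	-1.5
Q8N987	N-terminal EF-hand calcium-binding protein 1	Cytoplasm	1	-1.6
Q13516	Oligodendrocyte transcription factor 2	Nucleus; Cytoplasm	1	-1.1
Q59GK5	Glutamate receptor, metabotropic 4 variant	Membrane	1	-1.4
Q16650	T-box brain protein 1	Nucleus	1	-1.8
Q504Y0	Zinc transporter ZIP12	Membrane	1	-1
P41225	Transcription factor SOX-3	Nucleus	1	-1.30
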