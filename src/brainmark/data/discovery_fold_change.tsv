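accession	protein_name	n_samples_sci_neg	n_samples_sci_pos	avg_sc_sci_neg	avg_sc_sci_pos	reported_ratio
Q9P273	Teneurin-3	7	3	51.9	8.0	6.5
P31949	Protein S100-A11	4	2	41.5	7.5	5.5
P16401	Histone H1.5	2	2	21.0	4.5	4.7
Q9UJ43	L-selectin	8	2	17.8	4.0	4.4
P50552	Vasodilator-stimulated phosphoprotein	5	3	15.8	4.0	4.0
P18206	Vinculin	7	3	34.3	10.3	3.3
P10599	Thioredoxin	7	2	44.1	13.5	3.3
P20851	C4b-binding protein beta chain	8	5	22.1	7.8	2.8
P02775	Platelet basic protein	8	7	174.7	65.0	2.7
P02745	Complement C1q subcomponent subunit A	5	2	19.4	7.5	2.6
Q9UK55	Protein Z-dependent protease inhibitor	6	4	19.5	8.3	2.4
Q92954	Proteoglycan 4	8	6	26.2	11.7	2.2
P02746	Complement C1q subcomponent subunit B	8	7	105.4	47.0	2.2
Q96IY4	Carboxypeptidase B2	7	4	14.3	6.5	2.2
P07360	Complement component C8 gamma chain	8	7	53.2	25.3	2.1
P02533	Keratin, type I cytoskeletal 14	7	5	43.6	20.8	2.1
P08670	Vimentin	5	4	12.6	6.3	2.0
Q96PD5	N-acetylmuramoyl-L-alanine amidase	8	7	305.0	153.0	2.0
Q6B823	Histone H4	3	2	5.0	10.0	0.5
Q96F45	Zinc finger protein 503	3	2	2.0	4.0	0.5
P02679	Fibrinogen gamma chain	8	7	92.1	185.9	0.5
Q9NQS1	Cell death regulator Aven	3	2	4.0	10.0	0.4
P02461	Collagen alpha-1(III) chain	3	2	3.7	9.5	0.4
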