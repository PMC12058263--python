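name	formula	linkage	chirality_class	n_alkylated
Phe	C9H11NO2	amide	chiral	false
BocK	C11H22N2O4	amide	chiral	false
N-Me-BocK	C12H24N2O4	amide	chiral	true
OH-BocK	C11H21NO5	ester_hydroxy	chiral	false
R-b2-OH-BocK	C12H23NO5	ester_hydroxy	chiral	false
S-b2-OH-BocK	C12H23NO5	ester_hydroxy	chiral	false
m-Br-Phe	C9H10BrNO2	amide	chiral	false
m-CF3-bma	C11H9F3O4	ester_malonate	prochiral	false
m-Br-bma	C10H9BrO4	ester_malonate	prochiral	false
m-CH3-bma	C11H12O4	ester_malonate	prochiral	false
Leu-Enk	C28H37N5O7	internal_standard	achiral	false
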