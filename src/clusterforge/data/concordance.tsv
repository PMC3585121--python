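# Genotype -> chemotype concordance cases, as stated in the comparative
# study's results: each row asserts a property of the prediction for one
# strain/pathway and records whether the observed chemistry agreed.
# assertion: contains | excludes | accumulating ; products separated by ';'
# status "expected-discordant" marks the E2368 ergot-alkaloid case, where
# the genes are present but not expressed, so prediction from gene content
# alone is expected to disagree with the observed chemistry.
strain	pathway	assertion	products	status	note
Ngi	EAS	contains	EN;LAH	consistent	lacked only lpsA and easH; EN and LAH producer
Ngi	EAS	excludes	ergopeptine	consistent	no ergopeptines without lpsA/easH
Ef1	EAS	contains	ergopeptine	consistent	ergovaline producer
Ef1	EAS	excludes	EN;LAH	consistent	lacks lpsC (and easO/easP)
Eel	EAS	accumulating	CC	consistent	first four pathway genes only
Ebe	LOL	accumulating	AcAP	consistent	inactive lolO (internal deletion)
Ef2	PER	excludes	PER	consistent	perA-deltaR* yields no peramine
Cpu	EAS	contains	ergopeptine;EN	consistent	two lpsA copies; EN predicted from gene content
Ef1	IDT	accumulating	LTM	consistent	lolitrem B producer
Nga	IDT	accumulating	PAX	consistent	paxilline producer
Pip	IDT	accumulating	TDK	consistent	terpendole producer
Eam	LOL	accumulating	NANL	consistent	lolN/lolM absent, lolP inactive
Ef2	LOL	accumulating	NFL	consistent	full LOL gene set
Ef2	EAS	contains	ergopeptine	expected-discordant	EAS genes present but not expressed; no ergot alkaloids observed
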