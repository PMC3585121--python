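# Alkaloid-gene genotypes of sequenced Clavicipitaceae isolates.
# Catalog genes with no row for a strain are absent.  Cells whose printed
# table alignment was ambiguous follow the Results prose; strains/cells not
# pinned by prose are best-effort transcriptions.
# status: functional | pseudogene ; copies: gene copy number ; variant: e.g. deltaR for perA-dR*
# strain keys: Ata=A. take MAFF-241224, Cfu=C. fusiformis PRL 1980, Cpa=C. paspali RRC-1481,
# Cpu=C. purpurea 20.1, Eam=E. amarillans E57, Ebe=E. brachyelytri E4804, Eel=E. elymi E56,
# Ef1=E. festucae Fl1, Ef2=E. festucae E2368, Egl=E. glyceriae E277/E2772, Et5=E. typhina E5819,
# Et8=E. typhina E8, Nga=N. gansuense E7080, Ngi=N. gansuense var. inebrians E818,
# Nun=N. uncinatum E167, Pip=P. ipomoeae IasaF13
strain	pathway	gene	status	copies	variant
Cfu	EAS	dmaW	functional	1
Cfu	EAS	easF	functional	1
Cfu	EAS	easE	functional	1
Cfu	EAS	easC	functional	1
Cfu	EAS	easD	functional	1
Cfu	EAS	easA	functional	1
Cfu	EAS	easG	functional	1
Cfu	EAS	cloA	functional	1
Cfu	EAS	easH	functional	1
Cfu	EAS	lpsB	pseudogene	1
Cfu	EAS	lpsC	pseudogene	1
Cpa	EAS	dmaW	functional	1
Cpa	EAS	easF	functional	1
Cpa	EAS	easE	pseudogene	1
Cpa	EAS	easC	functional	1
Cpa	EAS	easD	functional	1
Cpa	EAS	easA	functional	1
Cpa	EAS	easG	functional	1
Cpa	EAS	cloA	functional	1
Cpa	EAS	easO	functional	1
Cpa	EAS	easP	functional	1
Cpa	EAS	lpsB	functional	1
Cpa	EAS	lpsC	functional	1
Cpu	EAS	dmaW	functional	1
Cpu	EAS	easF	functional	1
Cpu	EAS	easE	functional	1
Cpu	EAS	easC	functional	1
Cpu	EAS	easD	functional	1
Cpu	EAS	easA	functional	1
Cpu	EAS	easG	functional	1
Cpu	EAS	cloA	functional	1
Cpu	EAS	easH	functional	2
Cpu	EAS	lpsA	functional	2
Cpu	EAS	lpsB	functional	1
Cpu	EAS	lpsC	functional	1
Eam	EAS	lpsA	pseudogene	1
Ebe	EAS	dmaW	functional	1
Ebe	EAS	easF	functional	1
Ebe	EAS	easE	functional	1
Ebe	EAS	easC	functional	1
Ebe	EAS	easD	pseudogene	1
Ebe	EAS	easG	pseudogene	1
Ebe	EAS	lpsA	pseudogene	1
Eel	EAS	dmaW	functional	1
Eel	EAS	easF	functional	1
Eel	EAS	easE	functional	1
Eel	EAS	easC	functional	1
Eel	EAS	easG	pseudogene	1
Ef1	EAS	dmaW	functional	1
Ef1	EAS	easF	functional	1
Ef1	EAS	easE	functional	1
Ef1	EAS	easC	functional	1
Ef1	EAS	easD	functional	1
Ef1	EAS	easA	functional	1
Ef1	EAS	easG	functional	1
Ef1	EAS	cloA	functional	1
Ef1	EAS	easH	functional	1
Ef1	EAS	lpsA	functional	1
Ef1	EAS	lpsB	functional	1
Ef2	EAS	dmaW	functional	1
Ef2	EAS	easF	functional	1
Ef2	EAS	easE	functional	1
Ef2	EAS	easC	functional	1
Ef2	EAS	easD	functional	1
Ef2	EAS	easA	functional	1
Ef2	EAS	easG	functional	1
Ef2	EAS	cloA	functional	1
Ef2	EAS	easH	functional	1
Ef2	EAS	lpsA	functional	1
Ef2	EAS	lpsB	functional	1
Egl	EAS	dmaW	functional	1
Egl	EAS	easF	functional	1
Egl	EAS	easE	functional	1
Egl	EAS	easC	functional	1
Egl	EAS	easD	functional	1
Egl	EAS	easA	functional	1
Egl	EAS	easG	functional	1
Egl	EAS	cloA	functional	1
Egl	EAS	easH	functional	1
Egl	EAS	lpsA	functional	1
Egl	EAS	lpsB	functional	1
Et5	EAS	dmaW	functional	1
Et5	EAS	easF	functional	1
Et5	EAS	easE	functional	1
Et5	EAS	easC	functional	1
Et5	EAS	easD	functional	1
Et5	EAS	easA	functional	1
Et5	EAS	easG	functional	1
Et5	EAS	cloA	functional	1
Et5	EAS	easH	functional	1
Et5	EAS	lpsA	functional	1
Et5	EAS	lpsB	functional	1
Ngi	EAS	dmaW	functional	1
Ngi	EAS	easF	functional	1
Ngi	EAS	easE	functional	1
Ngi	EAS	easC	functional	1
Ngi	EAS	easD	functional	1
Ngi	EAS	easA	functional	1
Ngi	EAS	easG	functional	1
Ngi	EAS	cloA	functional	1
Ngi	EAS	easO	functional	1
Ngi	EAS	easP	functional	1
Ngi	EAS	lpsB	functional	1
Ngi	EAS	lpsC	functional	1
Pip	EAS	dmaW	functional	1
Pip	EAS	easF	functional	1
Pip	EAS	easE	functional	1
Pip	EAS	easC	functional	1
Pip	EAS	easD	functional	1
Pip	EAS	easA	functional	1
Pip	EAS	easG	functional	1
Pip	EAS	cloA	functional	1
Pip	EAS	easH	functional	1
Pip	EAS	easO	functional	1
Pip	EAS	easP	functional	1
Pip	EAS	lpsA	functional	1
Pip	EAS	lpsB	functional	1
Pip	EAS	lpsC	functional	1
Ata	IDT	idtM	functional	1
Ata	IDT	idtS	functional	1
Ata	IDT	idtG	pseudogene	1
Ata	IDT	idtB	functional	1
Ata	IDT	idtC	functional	1
Ata	IDT	idtF	functional	1
Ata	IDT	idtP	functional	1
Ata	IDT	idtQ	functional	1
Cpa	IDT	idtG	functional	1
Cpa	IDT	idtM	functional	1
Cpa	IDT	idtB	functional	1
Cpa	IDT	idtC	functional	1
Cpa	IDT	idtS	functional	1
Cpa	IDT	idtF	functional	1
Cpa	IDT	idtP	functional	1
Cpa	IDT	idtQ	functional	1
Cpu	IDT	idtM	functional	1
Cpu	IDT	idtB	functional	1
Cpu	IDT	idtC	functional	1
Cpu	IDT	idtS	functional	1
Cpu	IDT	idtP	functional	1
Cpu	IDT	idtQ	functional	1
Ef1	IDT	idtG	functional	1
Ef1	IDT	idtM	functional	1
Ef1	IDT	idtB	functional	1
Ef1	IDT	idtC	functional	1
Ef1	IDT	idtS	functional	1
Ef1	IDT	idtP	functional	1
Ef1	IDT	idtQ	functional	1
Ef1	IDT	idtF	functional	1
Ef1	IDT	idtK	functional	1
Ef1	IDT	ltmE	functional	1
Ef1	IDT	ltmJ	functional	1
Ef2	IDT	idtB	functional	1
Ef2	IDT	idtC	functional	1
Ef2	IDT	idtF	functional	1
Ef2	IDT	idtP	functional	1
Ef2	IDT	idtQ	functional	1
Nga	IDT	idtG	functional	1
Nga	IDT	idtM	functional	1
Nga	IDT	idtB	functional	1
Nga	IDT	idtC	functional	1
Nga	IDT	idtS	functional	1
Nga	IDT	idtP	functional	1
Nga	IDT	idtQ	functional	1
Nga	IDT	idtF	functional	1
Nga	IDT	idtK	pseudogene	1
Pip	IDT	idtG	functional	1
Pip	IDT	idtM	functional	1
Pip	IDT	idtB	functional	1
Pip	IDT	idtC	functional	1
Pip	IDT	idtS	functional	1
Pip	IDT	idtP	functional	1
Pip	IDT	idtQ	functional	1
Pip	IDT	idtF	functional	1
Pip	IDT	idtK	functional	1
Eam	LOL	lolF	functional	1
Eam	LOL	lolC	functional	1
Eam	LOL	lolD	functional	1
Eam	LOL	lolO	functional	1
Eam	LOL	lolA	functional	1
Eam	LOL	lolU	functional	1
Eam	LOL	lolP	pseudogene	1
Eam	LOL	lolT	functional	1
Eam	LOL	lolE	functional	1
Ebe	LOL	lolF	functional	1
Ebe	LOL	lolC	functional	1
Ebe	LOL	lolD	functional	1
Ebe	LOL	lolO	pseudogene	1
Ebe	LOL	lolA	functional	1
Ebe	LOL	lolU	functional	1
Ebe	LOL	lolT	functional	1
Ebe	LOL	lolE	functional	1
Ef2	LOL	lolF	functional	1
Ef2	LOL	lolC	functional	1
Ef2	LOL	lolD	functional	1
Ef2	LOL	lolO	functional	1
Ef2	LOL	lolA	functional	1
Ef2	LOL	lolU	functional	1
Ef2	LOL	lolP	functional	1
Ef2	LOL	lolT	functional	1
Ef2	LOL	lolE	functional	1
Ef2	LOL	lolN	functional	1
Ef2	LOL	lolM	functional	1
Egl	LOL	lolF	functional	1
Egl	LOL	lolC	functional	1
Egl	LOL	lolD	functional	1
Egl	LOL	lolO	functional	1
Egl	LOL	lolA	functional	1
Egl	LOL	lolU	functional	1
Egl	LOL	lolT	functional	1
Egl	LOL	lolE	functional	1
Egl	LOL	lolN	pseudogene	1
Nga	LOL	lolD	pseudogene	1
Nga	LOL	lolO	pseudogene	1
Nga	LOL	lolU	pseudogene	1
Nga	LOL	lolA	functional	1
Nun	LOL	lolF	functional	2
Nun	LOL	lolC	functional	2
Nun	LOL	lolD	functional	2
Nun	LOL	lolO	functional	2
Nun	LOL	lolA	functional	2
Nun	LOL	lolU	functional	2
Nun	LOL	lolP	functional	2
Nun	LOL	lolT	functional	2
Nun	LOL	lolE	functional	2
Nun	LOL	lolN	functional	1
Nun	LOL	lolM	functional	1
Eam	PER	perA	functional	1
Ebe	PER	perA	functional	1
Eel	PER	perA	functional	1
Ef1	PER	perA	functional	1
Ef2	PER	perA	functional	1	deltaR
Et5	PER	perA	functional	1	deltaR
Et8	PER	perA	functional	1
Pip	PER	perA	pseudogene	1
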