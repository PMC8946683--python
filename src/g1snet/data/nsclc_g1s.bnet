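# nsclc_g1s: Boolean model of the NSCLC G1/S checkpoint
# miR-34a vs the lncRNA sponges ANRIL and UFC1; single input DNA_Damage
# generated from g1snet.model.RULES -- edit there, not here
# kind: DNA_Damage input DNA Damage
# kind: ATM internal ATM
# kind: p53 internal p53
# kind: Mdm2 internal Mdm2
# kind: Wip1 internal Wip1
# kind: p53_A internal p53-A
# kind: p53_K internal p53-K
# kind: p53_INP1 internal p53-INP1
# kind: p21 internal p21
# kind: Bax internal Bax
# kind: Casp3 internal Caspase3
# kind: BCL2 internal BCL2
# kind: miR34a internal miR-34a
# kind: ANRIL internal ANRIL
# kind: UFC1 internal UFC1
# kind: EZH2 internal EZH2
# kind: PTEN internal PTEN
# kind: AKT internal AKT
# kind: KLF2 internal KLF2
# kind: Myc internal Myc
# kind: HDAC1 internal HDAC1
# kind: Sirt1 internal Sirt-1
# kind: E2F1 internal E2F1
# kind: Cdc25A internal Cdc25A
# kind: CDK46_CycD internal CDK46/CycD
# kind: CDK2_CycE internal CDK2/CycE
# kind: RB internal RB
# kind: Proliferation output Proliferation
# kind: Senescence output Senescence
# kind: Apoptosis output Apoptosis
# edge: AKT Mdm2 +
# edge: AKT Myc +
# edge: ANRIL EZH2 +
# edge: ANRIL miR34a -
# edge: ATM Cdc25A -
# edge: ATM E2F1 +
# edge: ATM Mdm2 -
# edge: ATM miR34a +
# edge: ATM p53 +
# edge: BCL2 Bax -
# edge: Bax Casp3 +
# edge: CDK2_CycE Proliferation +
# edge: CDK2_CycE RB -
# edge: CDK46_CycD Proliferation +
# edge: CDK46_CycD RB -
# edge: Casp3 Apoptosis +
# edge: Casp3 E2F1 -
# edge: Casp3 Proliferation -
# edge: Casp3 Senescence -
# edge: Casp3 miR34a -
# edge: Casp3 p21 -
# edge: Cdc25A CDK2_CycE +
# edge: Cdc25A Proliferation +
# edge: DNA_Damage ATM +
# edge: E2F1 ANRIL +
# edge: E2F1 ATM +
# edge: E2F1 CDK2_CycE +
# edge: E2F1 Cdc25A +
# edge: E2F1 Myc +
# edge: E2F1 Sirt1 +
# edge: E2F1 UFC1 +
# edge: E2F1 p53_A -
# edge: EZH2 KLF2 -
# edge: EZH2 PTEN -
# edge: EZH2 miR34a -
# edge: HDAC1 ATM -
# edge: HDAC1 p21 -
# edge: KLF2 p21 +
# edge: Mdm2 p53 -
# edge: Myc ANRIL +
# edge: Myc CDK46_CycD +
# edge: Myc Cdc25A +
# edge: Myc E2F1 +
# edge: Myc HDAC1 +
# edge: Myc p21 -
# edge: PTEN AKT -
# edge: RB E2F1 -
# edge: Sirt1 E2F1 -
# edge: UFC1 EZH2 +
# edge: UFC1 miR34a -
# edge: Wip1 ATM -
# edge: Wip1 p53_INP1 -
# edge: miR34a BCL2 -
# edge: miR34a CDK2_CycE -
# edge: miR34a CDK46_CycD -
# edge: miR34a Cdc25A -
# edge: miR34a E2F1 -
# edge: miR34a HDAC1 -
# edge: miR34a Myc -
# edge: miR34a Sirt1 -
# edge: p21 CDK2_CycE -
# edge: p21 CDK46_CycD -
# edge: p21 Casp3 -
# edge: p21 Myc -
# edge: p21 Proliferation -
# edge: p21 Senescence +
# edge: p21 p53_K -
# edge: p53 BCL2 -
# edge: p53 EZH2 -
# edge: p53 Mdm2 +
# edge: p53 Myc -
# edge: p53 PTEN +
# edge: p53 Wip1 +
# edge: p53 miR34a +
# edge: p53 p53_A +
# edge: p53 p53_K +
# edge: p53_A Wip1 +
# edge: p53_A p21 +
# edge: p53_A p53_INP1 +
# edge: p53_A p53_K -
# edge: p53_INP1 p53_A -
# edge: p53_K Bax +
# edge: p53_K p53_A -
targets, factors
DNA_Damage, DNA_Damage
ATM, DNA_Damage & (E2F1 | !(Wip1 & HDAC1))
p53, ATM & !Mdm2
Mdm2, (p53 | AKT) & !ATM
Wip1, p53 & p53_A
p53_A, p53 & !p53_K & !p53_INP1 & !E2F1
p53_K, p53 & !p53_A & !p21
p53_INP1, p53_A & !Wip1
p21, (p53_A | KLF2) & !Myc & !HDAC1 & !Casp3
Bax, p53_K & !BCL2
Casp3, Bax & !p21
BCL2, !miR34a & !p53
miR34a, ATM & p53 & !Casp3 | (ATM | p53) & !ANRIL & !UFC1 & !EZH2
ANRIL, E2F1 | Myc
UFC1, E2F1
EZH2, ANRIL | UFC1 | !p53
PTEN, p53 | !EZH2
AKT, !PTEN
KLF2, !EZH2
Myc, (E2F1 | AKT) & !miR34a & !p21 & !p53
HDAC1, Myc | !miR34a
Sirt1, E2F1 & !miR34a
E2F1, !miR34a & !Casp3 & (Myc & !RB | ATM & !Sirt1)
Cdc25A, (E2F1 | Myc) & !miR34a & !ATM
CDK46_CycD, Myc & !miR34a & !p21
CDK2_CycE, E2F1 & Cdc25A & !miR34a & !p21
RB, !CDK46_CycD & !CDK2_CycE
Proliferation, CDK46_CycD & CDK2_CycE & Cdc25A & !p21 & !Casp3
Senescence, p21 & !Casp3
Apoptosis, Casp3
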