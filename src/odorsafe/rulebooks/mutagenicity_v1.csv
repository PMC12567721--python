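# rulebook: mutagenicity
# version: 1.0
# Structural alerts for in vitro (Ames) bacterial mutagenicity, after the
# ISS / Benigni-Bossa rule base. Only the binary outcome (any alert vs none)
# feeds TTC assignment. Carcinogenicity-only alerts are intentionally absent.
alert_id,description,smarts
SA1,Acyl halide,"[CX3](=[OX1])[F,Cl,Br,I]"
SA2,Alkyl or benzyl ester of sulfonic or phosphonic acid,"[CX4][OX2][$([SX4](=[OX1])(=[OX1])),$([PX4](=[OX1]))]"
SA3,N-methylol derivative,[NX3][CX4H2][OX2H]
SA4,Monohaloalkene,"[CX3]=[CX3][F,Cl,Br,I]"
SA5,Sulfur or nitrogen mustard,"[NX3,SX2]([CX4H2][CX4H2][F,Cl,Br,I])[CX4H2][CX4H2][F,Cl,Br,I]"
SA6,beta-propiolactone or beta-propiosultone,"[$([CX3]1(=[OX1])[OX2][CX4][CX4]1),$([SX4]1(=[OX1])(=[OX1])[OX2][CX4][CX4]1)]"
SA7,Epoxide or aziridine,"[#6]1[#6][#8X2,#7X3]1"
SA8,Aliphatic halogen,"[CX4][Cl,Br,I]"
SA9,Alkyl nitrite,[CX4][OX2][NX2]=[OX1]
SA10,"alpha,beta-unsaturated carbonyl","[$([CX3]=[CX3][CX3]=[OX1]),$([CX2]#[CX2][CX3]=[OX1])]"
SA11,Simple aldehyde,[CX3H1]=[OX1]
SA12,Quinone,"[$([OX1]=[CX3]1[CX3]=[CX3][CX3](=[OX1])[CX3]=[CX3]1),$([OX1]=[CX3]1[CX3]=[CX3][CX3]=[CX3][CX3]1=[OX1])]"
SA13,Hydrazine,"[NX3;!$(NC=[O,S]);!$(N~[n,c])][NX3;!$(NC=[O,S])]"
SA14,Aliphatic azo or azoxy,"[$([CX4][NX2]=[NX2][CX4]),$([NX2]=[NX3+][OX1-]),$([NX2]=[NX3]=[OX1])]"
SA15,Isocyanate or isothiocyanate,"[NX2]=[CX2]=[OX1,SX1]"
SA16,Alkyl carbamate or thiocarbamate,"[NX3][CX3](=[OX1,SX1])[OX2][CX4]"
SA18,Polycyclic aromatic hydrocarbon (3+ fused rings),"[$(c1ccc2ccc3ccccc3c2c1),$(c1ccc2cc3ccccc3cc2c1)]"
SA19,Heterocyclic polycyclic aromatic system (3+ fused rings),"[$(c1ccc2c(c1)oc1ccccc12),$(c1ccc2c(c1)[nH]c1ccccc12),$(c1ccc2c(c1)sc1ccccc12),$(c1ccc2nc3ccccc3cc2c1)]"
SA21,Alkyl or aryl N-nitroso,[NX3][NX2]=[OX1]
SA22,Azide or triazene,"[$([NX2]=[NX2+]=[NX1-]),$([NX3][NX2]=[NX2])]"
SA23,Aliphatic N-nitro,"[NX3][$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]"
SA24,"alpha,beta-unsaturated alkoxy (enol ether)",[CX3]=[CX3][OX2][#6]
SA25,Aromatic nitroso,[cX3][NX2]=[OX1]
SA26,Aromatic ring N-oxide,"[$([nX3+][OX1-]),$([nX3]=[OX1])]"
SA27,Nitro-aromatic,"[cX3][$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]"
SA28,Primary aromatic amine or hydroxylamine,"[$([cX3][NX3H2]),$([cX3][NX3H1][OX2H1])]"
SA28bis,Aromatic mono- or dialkylamine,"[$([cX3][NX3H1][CX4]),$([cX3][NX3]([CX4])[CX4])]"
SA28ter,Aromatic N-acylamine,[cX3][NX3H1][CX3]=[OX1]
SA29,Aromatic diazonium or azo,"[$([cX3][NX2+]#[NX1]),$([cX3][NX2]=[NX2][cX3])]"
SA30,Coumarin or furocoumarin,"[$([OX1]=c1ccc2ccccc2o1),$([OX1]=[CX3]1[CX3]=[CX3]c2ccccc2[OX2]1)]"
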