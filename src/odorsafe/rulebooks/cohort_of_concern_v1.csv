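# rulebook: cohort_of_concern
# version: 1.0
# Chemical classes for which TTC-based screening is invalid; any match marks
# the record out-of-domain (the method must not be used for these classes):
# organophosphates, dioxin-like, alkyl azoxy, N-nitrosamines, aflatoxin-like.
alert_id,description,smarts
COC_OP,Organophosphate (P(V) with P=O or P=S),"[$([PX4](=[OX1,SX1]))]"
COC_DIOXIN,Dibenzo-p-dioxin skeleton,c1ccc2c(c1)Oc1ccccc1O2
COC_AZOXY,Alkyl azoxy,"[$([CX4][NX2]=[NX3+][OX1-]),$([CX4][NX2]=[NX3]=[OX1]),$([CX4][NX3+]([OX1-])=[NX2]),$([CX4][NX3](=[OX1])=[NX2])]"
COC_NITROSAMINE,N-nitrosamine,[NX3][NX2]=[OX1]
COC_AFLATOXIN,Aflatoxin-like fused bisfuran,[#6]1[#8][#6]2[#8][#6]=[#6][#6]2[#6]1
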