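# rulebook: cramer
# version: 1.0
# Condensed encoding of the Cramer structural-class decision tree for
# oral/systemic toxicity concern, adapted to the volatile-odorant chemical
# space. Question ids follow the published numbering where the question is
# retained; QA-suffixed ids are condensation points. Each row is one yes/no
# question: predicate names refer to the registry in odorsafe.cramer;
# successors are question ids or terminal classes CLASS_I/CLASS_II/CLASS_III.
question_id,text,predicate,if_yes,if_no
Q1,Is the substance a normal constituent of the body or a harmless product of metabolism?,body_constituent,CLASS_I,Q2
Q2,Does it contain functional groups associated with enhanced toxicity (aliphatic secondary amine; cyano; N-nitroso; diazo; triazeno; quaternary nitrogen)?,enhanced_toxicity_groups,CLASS_III,Q3
Q3,Does it contain elements other than C/H/O/N or other than divalent sulfur?,unusual_elements,CLASS_III,Q5
Q5,Is it a simply branched acyclic aliphatic hydrocarbon or a common carbohydrate?,simple_hydrocarbon_or_sugar,CLASS_I,Q7
Q7,Is it heterocyclic?,heterocyclic,Q7A,Q19
Q7A,Does it contain a heteroaromatic ring?,heteroaromatic,CLASS_III,Q8
Q8,Is it a lactone or cyclic diester?,lactone,Q9,Q10
Q9,"Is the lactone alpha,beta-unsaturated or fused to an aromatic ring?",unsaturated_lactone,CLASS_III,CLASS_II
Q10,Is it a saturated oxygen heterocycle bearing only innocuous substituents (hydrocarbon chains; hydroxyl; ether; carbonyl; carboxyl)?,innocuous_o_heterocycle,CLASS_II,CLASS_III
Q19,Does it contain an aromatic carbocycle?,has_aromatic_ring,Q6,Q20
Q6,Is it a mononuclear benzene derivative bearing only innocuous substituents (hydrocarbon chains; hydroxyl; ether; carbonyl; carboxyl; ester)?,innocuous_benzene,CLASS_I,CLASS_III
Q20,Is it an open-chain or alicyclic structure bearing only readily metabolized functional groups (hydroxyl; ether; aldehyde; ketone; carboxylic acid; ester; alkene/alkyne; thiol; sulfide)?,innocuous_aliphatic_groups,CLASS_I,CLASS_III
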