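# Phosphopeptide fixtures: four phosphorylated disordered peptides.
# Phosphosite positions are 1-based and shipped here as explicit,
# editable configuration (bCPP and Stath sites follow the standard
# phosphoforms beta-casein 1-25 pS15/pS17/pS18/pS19 and statherin pS2/pS3).
peptides:
  Tau1:
    protein: Tau 173-183 (with 3 flanking residues)
    sequence: CAKTPPAPKTPPAW
    phosphosites: [4, 10]       # pT175, pT181
  Tau2:
    protein: Tau 225-246
    sequence: KVAVVRTPPKSPSSAKSRLQTA
    phosphosites: [7, 11, 13, 14]   # pT231, pS235, pS237, pS238
  bCPP:
    protein: beta-casein 1-25
    sequence: RELEELNVPGEIVESLSSSEESITR
    phosphosites: [15, 17, 18, 19]  # pS15, pS17, pS18, pS19
  Stath:
    protein: Statherin
    sequence: DSSEEKFLRRIGRFGYGYGPYQPVPEQPLYPQPYQPQYQQYTF
    phosphosites: [2, 3]        # pS2, pS3
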