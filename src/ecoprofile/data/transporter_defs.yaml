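# Curated sugar-transporter system definitions.
#
# Each system lists its required machinery roles and the KEGG KO ids that
# satisfy each role: ABC importers need a substrate-binding protein (SBP),
# transmembrane domains (TMD) and a nucleotide-binding domain (NBD);
# PTS systems need enzyme I (EI), the phosphocarrier HPr, and the
# substrate-specific enzyme II complex (EII).  EI and HPr are genome-global
# (one copy serves all EII complexes), so the same KO ids appear in every
# PTS system.  KO ids were curated from KEGG module definitions; the file
# is data, reviewable and overridable.
systems:
  - id: abc_maltose
    kind: ABC
    substrate: maltose/maltodextrin
    roles:
      SBP: [K10108]                 # malE
      TMD: [K10109, K10110]         # malF, malG
      NBD: [K10111]                 # malK
  - id: abc_glucose_mannose
    kind: ABC
    substrate: glucose/mannose
    roles:
      SBP: [K17315]                 # gtsA
      TMD: [K17316, K17317]         # gtsB, gtsC
      NBD: [K17318]                 # gtsD
  - id: abc_ribose
    kind: ABC
    substrate: ribose
    roles:
      SBP: [K10439]                 # rbsB
      TMD: [K10440]                 # rbsC
      NBD: [K10441]                 # rbsA
  - id: pts_glucose
    kind: PTS
    substrate: glucose
    roles:
      EI:  [K08483]                 # ptsI
      HPr: [K02784]                 # ptsH
      EII: [K02777, K02778, K02779] # crr / ptsG
  - id: pts_glcnac
    kind: PTS
    substrate: GlcNAc
    roles:
      EI:  [K08483]
      HPr: [K02784]
      EII: [K02802, K02803, K02804] # nagE
  - id: pts_fructose
    kind: PTS
    substrate: fructose
    roles:
      EI:  [K08483]
      HPr: [K02784]
      EII: [K02768, K02769, K02770] # fruA/fruB
  - id: pts_maltose_glucose
    kind: PTS
    substrate: maltose/glucose
    roles:
      EI:  [K08483]
      HPr: [K02784]
      EII: [K02790, K02791]         # malX
  - id: pts_trehalose
    kind: PTS
    substrate: trehalose
    roles:
      EI:  [K08483]
      HPr: [K02784]
      EII: [K02817, K02818, K02819] # treB
  - id: pts_mannitol
    kind: PTS
    substrate: mannitol
    roles:
      EI:  [K08483]
      HPr: [K02784]
      EII: [K02798, K02799, K02800] # mtlA
  - id: pts_galnac
    kind: PTS
    substrate: N-acetylgalactosamine
    roles:
      EI:  [K08483]
      HPr: [K02784]
      EII: [K02744, K02745, K02746] # agaV/agaW/agaE-type
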