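# Machinery models: mandatory gene roles per secretion system, pilus and
# flagellum, following MacSyFinder/TXSScan-style model definitions (the
# T2SS model carries 13 mandatory genes and the T4SS_G model 17, matching
# the completeness fractions used in reporting).  Role names are the
# conventional gene symbols; the scanner's detection table must use the
# same names.
models:
  - id: T1SS
    mandatory: [abc, mfp, omf]
  - id: T2SS
    mandatory: [gspC, gspD, gspE, gspF, gspG, gspH, gspI, gspJ, gspK, gspL, gspM, gspN, gspO]
  - id: T3SS
    mandatory: [sctC, sctJ, sctN, sctQ, sctR, sctS, sctT, sctU, sctV]
  - id: T4SS_F
    mandatory: [virB1, virB2, virB3, virB4, virB5, virB6, virB8, virB9, virB10, virB11, virD4]
  - id: T4SS_G
    mandatory: [tfc2, tfc3, tfc5, tfc6, tfc7, tfc8, tfc9, tfc10, tfc11, tfc12,
                tfc13, tfc14, tfc15, tfc16, tfc17, tfc18, tfc19]
  - id: T5SS
    mandatory: [passenger, translocator, signal_peptide]
  - id: T6SS
    mandatory: [tssA, tssB, tssC, hcp, tssE, tssF, tssG, clpV, tssJ, tssK, tssL, tssM, vgrG]
  - id: Flagellum
    mandatory: [fliE, fliF, fliG, fliM, fliN, flgB, flgC, flhA, flhB, fliI, fliP, fliQ, fliR, motA, motB]
  - id: Tad
    mandatory: [tadA, tadB, tadC, tadZ, rcpA, rcpC, flp, tadE, tadF, tadG]
  - id: MSH
    mandatory: [mshA, mshE, mshG, mshL, mshM, mshN, mshB, mshC, mshD, mshJ, mshK]
  - id: T4aP
    mandatory: [pilA, pilB, pilC, pilD, pilM, pilN, pilO, pilP, pilQ, pilT, pilU]
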