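# Ecological gene panels.  Marker KO ids are a curation against KEGG
# orthology; matching defaults to KO (gene-symbol matching against product
# text is available but annotation-tool dependent).
#
# The osmoadaptation panel is satisfied when at least one osmoprotectant
# transport or biosynthesis subsystem is complete; nitrate reduction (to
# ammonia, nap/nir route) requires all four genes; the remaining panels are
# report-only copy-number screens.
panels:
  - id: osmoadaptation
    verdict_rule: any_complete_subsystem
    markers:
      # secondary response: osmoprotectant transporters
      - {name: betT, ids: [K02168], subsystem: choline_transport}
      - {name: proV, ids: [K02000], subsystem: glycine_betaine_transport}
      - {name: proW, ids: [K02001], subsystem: glycine_betaine_transport}
      - {name: proX, ids: [K02002], subsystem: glycine_betaine_transport}
      - {name: caiT, ids: [K05245], subsystem: carnitine_transport}
      - {name: proP, ids: [K03762], subsystem: proP_permease}
      # biosynthesis routes
      - {name: betA, ids: [K00108], subsystem: glycine_betaine_synthesis}
      - {name: betB, ids: [K00130], subsystem: glycine_betaine_synthesis}
      - {name: proB, ids: [K00931], subsystem: proline_synthesis}
      - {name: proA, ids: [K00147], subsystem: proline_synthesis}
      - {name: proC, ids: [K00286], subsystem: proline_synthesis}
      - {name: ectA, ids: [K06718], subsystem: ectoine_synthesis}
      - {name: ectB, ids: [K00836], subsystem: ectoine_synthesis}
      - {name: ectC, ids: [K06720], subsystem: ectoine_synthesis}
      - {name: otsA, ids: [K00697], subsystem: trehalose_synthesis_otsAB}
      - {name: otsB, ids: [K01087], subsystem: trehalose_synthesis_otsAB}
      - {name: treS, ids: [K05343], subsystem: trehalose_synthesis_treS}
      - {name: treY, ids: [K06044], subsystem: trehalose_synthesis_treYZ}
      - {name: treZ, ids: [K01236], subsystem: trehalose_synthesis_treYZ}
  - id: potassium_uptake
    verdict_rule: report_only
    markers:
      - {name: kdpA, ids: [K01546], subsystem: kdp}
      - {name: kdpB, ids: [K01547], subsystem: kdp}
      - {name: kdpC, ids: [K01548], subsystem: kdp}
      - {name: kdpD, ids: [K07646], subsystem: kdp}
      - {name: kdpE, ids: [K07667], subsystem: kdp}
      - {name: trkA, ids: [K03499], subsystem: trk}
      - {name: trkH, ids: [K03498], subsystem: trk}
      - {name: kup,  ids: [K03549], subsystem: kup}
  - id: nitrate_reduction
    verdict_rule: all_required
    markers:
      - {name: napA, ids: [K02567]}
      - {name: napB, ids: [K02568]}
      - {name: nirB, ids: [K00362]}
      - {name: nirD, ids: [K00363]}
  - id: fermentation_end_products
    verdict_rule: report_only
    markers:
      - {name: ldhA, ids: [K03778], subsystem: lactate}
      - {name: lldD, ids: [K00101], subsystem: lactate}
      - {name: ackA, ids: [K00925], subsystem: acetate}
      - {name: pta,  ids: [K13788], subsystem: acetate}
      - {name: frdA, ids: [K00244], subsystem: fumarate_succinate}
      - {name: fumB, ids: [K01677], subsystem: fumarate_succinate}
      - {name: gltA, ids: [K01647], subsystem: citrate}
      - {name: mdh,  ids: [K00024], subsystem: malate}
  - id: chemotaxis_signaling
    verdict_rule: report_only
    markers:
      - {name: cheA, ids: [K03407]}
      - {name: cheW, ids: [K03408]}
      - {name: cheV, ids: [K03415]}
      - {name: cheB, ids: [K03412]}
      - {name: cheR, ids: [K00575]}
      - {name: cheD, ids: [K03411]}
      - {name: cheY, ids: [K03413]}
      - {name: cheZ, ids: [K03414]}
      - {name: cheX, ids: [K03409]}
      - {name: fliG, ids: [K02410]}
      - {name: fliM, ids: [K02416]}
      - {name: fliN, ids: [K02417]}
      - {name: motA, ids: [K02556]}
      - {name: motB, ids: [K02557]}
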