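# ROS-defence enzymes and high-affinity oxidase complexes, matched by COG
# family id.  Multi-COG complexes count min(copies per member): every
# listed family must be present for the complex to count.
# Groups: "ros" = antioxidant enzymes; "high_affinity" = cytochromes able
# to harvest O2 at nanomolar concentrations (their presence flags a
# microaerophilic capability).
complexes:
  - {name: catalase,               cog_ids: [COG0376], group: ros}
  - {name: glutathione_peroxidase, cog_ids: [COG0386], group: ros}
  - {name: peroxidase_COG1858,     cog_ids: [COG1858], group: ros}
  - {name: peroxidase_COG2128,     cog_ids: [COG2128], group: ros}
  - {name: peroxidase_COG2837,     cog_ids: [COG2837], group: ros}
  - {name: cytochrome_cbb3,        cog_ids: [COG2010, COG4736, COG2993, COG3278], group: high_affinity}
  - {name: cytochrome_bd,          cog_ids: [COG1294, COG1271], group: high_affinity}
  - {name: cytochrome_b562,        cog_ids: [COG3783], group: high_affinity}
  - {name: cytochrome_c_oxidase,   cog_ids: [COG1845, COG0843, COG1622], group: high_affinity}
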