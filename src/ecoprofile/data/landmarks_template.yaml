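# Trophic landmark template: the 33 COG (sub)categories scored along the
# copiotroph-oligotroph axis, 14 with direction '+' (higher normalised gene
# counts indicate copiotrophy) and 19 with direction '-' (the opposite).
#
# The numeric reference values ("average copiotroph" / "average oligotroph")
# come from the published landmark scheme and are NOT redistributed here:
# every oligotroph_value / copiotroph_value below is a null placeholder the
# user must fill in from that scheme before scoring real genomes.  Category
# ids marked FILL_ME likewise stand for scheme entries not reproduced here.
# Directions on named entries are best-effort and should be verified against
# the same source.  All tests of this package use synthetic landmark sets.
unit: per_mb
landmarks:
  - {category: COG_1263, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_3325, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_0625, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_1680, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_1804, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_0183, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_1028, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_0318, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_1024, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_1960, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: Q, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: I, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_13, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_14, direction: "+", oligotroph_value: null, copiotroph_value: null}
  - {category: V, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: K, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: T, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: N, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_0737, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_2124, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_0583, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: COG_3710, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_23, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_24, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_25, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_26, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_27, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_28, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_29, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_30, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_31, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_32, direction: "-", oligotroph_value: null, copiotroph_value: null}
  - {category: FILL_ME_33, direction: "-", oligotroph_value: null, copiotroph_value: null}
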