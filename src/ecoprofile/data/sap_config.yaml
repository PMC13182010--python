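# Sugar-Acid Preference configuration.
#
# The coefficients weight the relative abundances of sugar- and acid-
# metabolism genes in SAP = tanh(s*S + a*A).  The KO sets below are a
# curated starter list (PTS components, glycolysis and sugar-catabolism
# steps on the sugar side; TCA-entry and carboxylic-acid uptake/catabolism
# on the acid side); users following a specific published curation should
# replace them with that list.  The sets must be non-empty and disjoint.
s: 60.76
a: -20.21
sugar_kos:
  - K08483   # ptsI, PTS enzyme I
  - K02784   # ptsH, phosphocarrier HPr
  - K02777   # crr, glucose PTS EIIA
  - K02778   # ptsG, glucose PTS EIIB
  - K02779   # ptsG, glucose PTS EIIC
  - K02802   # nagE, GlcNAc PTS EIIA
  - K02803   # nagE, GlcNAc PTS EIIB
  - K02804   # nagE, GlcNAc PTS EIIC
  - K00845   # glk, glucokinase
  - K01810   # pgi, glucose-6-phosphate isomerase
  - K00850   # pfkA, 6-phosphofructokinase
  - K01623   # fbaB, fructose-bisphosphate aldolase (class I)
  - K01624   # fbaA, fructose-bisphosphate aldolase (class II)
  - K00886   # ppgK, polyphosphate glucokinase
  - K01222   # celF, 6-phospho-beta-glucosidase
  - K05349   # bglX, beta-glucosidase
  - K01190   # lacZ, beta-galactosidase
  - K01443   # nagA, GlcNAc-6-P deacetylase
  - K02564   # nagB, glucosamine-6-P deaminase
  - K00847   # scrK, fructokinase
  - K01835   # pgm, phosphoglucomutase
acid_kos:
  - K01647   # gltA, citrate synthase
  - K01681   # acnA, aconitase
  - K00031   # icd, isocitrate dehydrogenase
  - K00024   # mdh, malate dehydrogenase
  - K01676   # fumA, fumarase
  - K00239   # sdhA, succinate dehydrogenase
  - K01902   # sucD, succinyl-CoA synthetase
  - K00116   # mqo, malate:quinone oxidoreductase
  - K03290   # citT-like citrate transporter (TRAP/2-HCT family)
  - K14445   # dcuA/dcuB-type anaerobic C4-dicarboxylate transporter
  - K11103   # actP, acetate permease
  - K01895   # acs, acetyl-CoA synthetase
  - K00925   # ackA, acetate kinase
  - K13788   # pta, phosphate acetyltransferase
  - K01610   # pckA, PEP carboxykinase
  - K00169   # porA, pyruvate:ferredoxin oxidoreductase
  - K00101   # lldD, L-lactate dehydrogenase (cytochrome)
  - K03777   # dld, D-lactate dehydrogenase
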