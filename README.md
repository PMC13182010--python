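# ecoprofile

Genome ecophysiological profiling for prokaryotes, built for comparative
genomics of small genome cohorts (e.g. all public genomes of one genus of
marine bacteria). Starting from per-gene functional annotation tables —
eggNOG-mapper COG assignments, BlastKOALA KEGG KOs, dbCAN CAZyme families,
MacSyFinder-style system detections — and externally computed ANI/dDDH
matrices, it infers each genome's ecological strategy without touching raw
sequence. The intended users are microbial ecologists characterising newly
sequenced isolates or genome collections.

## What it computes

**COG profiles.** Genes per COG category per genome (genes without a
category go to a derived `unknown` column), category Z-scores across the
cohort, `z = (x − µ)/σ` with population σ, and coefficient-of-variation
bands (CV ≤ 5% low, ≥ 10% high).

**Trophic strategy.** Each genome's normalised gene count in 33 scored COG
(sub)categories is compared to two reference landmarks, an "average
copiotroph" and an "average oligotroph". In 14 categories higher counts
indicate copiotrophy (direction `+`), in 19 the opposite (`−`). A value
strictly beyond the copiotroph landmark on the copiotrophic side calls the
category copiotrophic; beyond the oligotroph landmark, oligotrophic;
between the landmarks (ties included), indeterminate. A strict majority of
copiotrophic calls without unanimity labels the genome a *moderate
copiotroph* (mirrored for oligotrophs). Reference landmark values are not
redistributable and ship as an editable placeholder template; all tests
run on synthetic landmark sets.

**Sugar–acid preference.** `SAP = tanh(s·S + a·A)` with `s = 60.76`,
`a = −20.21`, where `S` and `A` are the fractions of ORFs assigned to
curated sugar- and acid-metabolism KO sets. SAP → +1 for sugar
specialists, −1 for acid specialists.

**Transporters.** ABC importers are complete only with substrate-binding
protein (SBP), transmembrane domains (TMD) and nucleotide-binding domain
(NBD); PTS systems with enzyme I, HPr and a substrate-specific EII
complex. A complete system is evidence the genome transports that sugar.
Transporter gene totals are expressed per Mb (1-decimal, half-up) and
ranked against a reference density distribution.

**Trait panels.** Configurable KO/COG marker panels for osmoadaptation
(compatible-solute transport and biosynthesis), potassium uptake, nitrate
reduction to ammonia (napAB + nirBD), fermentation end products, ROS
defence and high-affinity oxidases (microaerophily flag), chemotaxis
(MCP/Aer counts).

**Machinery adjudication.** Secretion systems (T1SS–T6SS, T4SS subtypes),
flagellum and type IV pili from detection tables: scanner and BRITE roles
are unioned, missing roles may be filled from a homology rescue table
restricted to a ±10-gene cluster neighbourhood (linear or circular
replicons), and each copy gets a provenance code (a–f) recording how
completeness was reached.

**CAZymes.** dbCAN family tallies (subfamilies collapse to families)
summed into polymer capabilities (agar, cellulose, chitin, pectin, xylan).

**Species delineation.** Genomes are conspecific when pairwise ANI > 95%
*and* dDDH > 70% (strict, configurable); putative species are connected
components of the pass graph, with the per-pair decision record exposed.

A synthetic-data module generates annotation tables (landmark-centred
Poisson gene counts per category), detection tables, CAZyme tables and
block-structured similarity matrices, so the whole pipeline is testable
without downloads.

## Worked example

```python
from ecoprofile import synthetic, trophic, species, transporters

# trophic scoring of a planted moderately-copiotrophic genome
landmarks = synthetic.synthetic_landmarks(seed=7)
spec = synthetic.SyntheticGenomeSpec("demo", archetype="moderate", seed=7)
table = synthetic.generate_annotation(spec, landmarks)
rec = synthetic.genome_record_for(spec, table)
counts = trophic.count_landmark_categories([table], landmarks)
norm = trophic.normalize_category_counts(counts, [rec], unit="per_mb")
summary = trophic.summarize_trophic(trophic.score_genomes(norm, landmarks), "demo")
print(f"{summary.genome_id}: {summary.n_copiotroph} copiotrophic, "
      f"{summary.n_oligotroph} oligotrophic, {summary.n_indeterminate} "
      f"indeterminate -> {summary.overall_label}")

print("density:", transporters.transporter_density(280, 4.8).density_display, "genes/Mb")
print("SAP(S=0.010, A=0.005):", round(trophic.sap_index(0.010, 0.005), 3))
```

prints

```
demo: 21 copiotrophic, 0 oligotrophic, 12 indeterminate -> moderate copiotroph
density: 58.3 genes/Mb
SAP(S=0.010, A=0.005): 0.467
```

21 of 33 scored categories fall beyond the copiotroph landmark — a strict
majority without unanimity, hence "moderate copiotroph". A genome with 280
transporter genes in 4.8 Mb carries 58.3 transporter genes per Mb, and a
genome where 1.0% of ORFs are sugar-metabolism genes versus 0.5%
acid-metabolism genes has a clearly sugar-oriented SAP of 0.467.

The CLI mirrors the library: `ecoprofile profile --config cohort.yaml
--out reports/`, plus `synth`, `delineate`, `density`, `sap` subcommands.

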