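# Methods

This note documents the models and procedures ecoprofile implements, the
parameters that matter, the synthetic-data generator's scope, numerical
choices, and known limitations.

## Input model

The pipeline operates downstream of annotation: it never runs Prokka,
eggNOG-mapper, BlastKOALA, dbCAN, TXSScan/ConjScan, OrthoANI or GGDC, only
parses their outputs (or tables in their dialects). Gene order along the
replicon is taken from file row order (0-based `rank`) and stands in for
coordinates; this is exact for single-replicon assemblies and approximate
across contig boundaries. COG category letters outside the single-letter
COG alphabet are dropped at parse time with a warning. When a gene carries
several COG letters it increments every corresponding category (the
eggNOG convention; a first-letter-only policy is available). Asymmetric
similarity matrices (GGDC output can be asymmetric) are symmetrised by the
arithmetic mean of the two entries and the diagonal forced to 100.

## COG profiles

Counts are genome × category with a derived `unknown` column for genes
lacking any category. Z-scores standardise each category across the
cohort: `z = (x − µ)/σ` with **population** σ (the bare formula carries no
ddof; sample σ is available via `ddof=1`). Categories constant across the
cohort (σ = 0) get z = 0, preserving heatmap neutrality. CV banding uses
`CV = 100·σ/µ`, bands `low` (CV ≤ 5, inclusive), `high` (CV ≥ 10,
inclusive), `intermediate` between; both thresholds are arguments.
Categories with µ = 0 are flagged `undefined` rather than binned.

## Trophic landmark scoring

Each of 33 scored categories (general letters or specific COG families)
has a direction and two reference values. The per-category rule is
deliberately conservative: a call requires the normalised value to lie
*strictly* beyond the relevant landmark; any value between the landmarks,
or exactly on one, is indeterminate. The overall label requires unanimity
for the pure labels and a strict majority for the "moderate" labels; equal
tallies are indeterminate. Summaries are emitted per genome and for the
across-genome mean profile.

Two normalisations are supported — counts per Mb and counts per ORF — and
both appear in practice for this scheme; per-Mb is the default here
because it is the convention under which this package's headline scoring
is defined. The choice is recorded in the output metadata, and landmark
values must be on the same scale (`unit` field).

The reference landmark values originate in a published training set of
copiotrophic and oligotrophic model organisms and are not redistributable;
the shipped `landmarks_template.yaml` carries the category scaffold with
null values that the user must fill in. Scoring with placeholder entries
raises immediately rather than returning silent zeros. All package tests
use fully-valued synthetic landmark sets.

## Sugar–acid preference

`SAP = tanh(s·S + a·A)`, `s = 60.76`, `a = −20.21`, with S and A the
fractions of ORFs whose KO falls in the configured sugar and acid KO sets
(disjoint, non-empty by validation; an empty configuration is an error
because it would silently yield SAP = 0 for every genome). The shipped KO
sets are a starter curation, not the original published list; users
following a specific curation should substitute their own.

Numerics: `tanh` saturates to exactly 1.0 in double precision once
`|s·S + a·A| ≳ 19`, which the coefficients reach near S ≈ 0.31. To keep
the index strictly inside (−1, 1) as defined, values are clamped to the
nearest representable interior double. Consequently strict monotonicity
holds only on the numerically injective region of tanh; outside it the
index is non-strictly monotone. Tests assert exactly this split.

## Transporter completeness, tallies, density

A role (SBP/TMD/NBD, EI/HPr/EII) is present iff at least one gene's KO is
in its acceptable set; a system is complete iff every role is present.
The role → KO maps are shipped YAML curated from KEGG module definitions
for the sugars the capability report covers; they are data, not code.

EI and HPr are genome-global — one copy phosphorylates all EII complexes —
so the sugar-gene tally deduplicates supporting genes across systems by
default (`count_global_once=True`); the alternative convention that
re-counts EI/HPr per complete system is available because published
per-genome tallies do not always state which convention they use.

Density is genes/Mb with 1-decimal **half-up** presentation (the raw value
is retained). Note that 294/4.8 = 61.25 sits exactly on a rounding
boundary; conventions differ there, which is why exact-boundary cases are
not used as checks. The reference ranking reports the fraction of a
user-supplied reference distribution strictly below the genome's density,
plus width-5 histogram bins for distribution plots.

## Trait panels

Markers match by KO id, COG family id, or (off by default, because product
strings are annotation-tool dependent) substring against the product text.
A subsystem is complete iff every member marker has ≥ 1 copy — e.g. the
glycine-betaine transporter requires proV + proW + proX jointly, and an
ectoine route carrying only ectB + ectC is reported partial, never
complete. Verdict rules: `any_complete_subsystem` (osmoadaptation: one
transport *or* biosynthesis route suffices), `all_required` (nitrate
reduction to ammonia needs napA, napB, nirB, nirD), `report_only`.
Multi-COG enzyme complexes (e.g. cytochrome cbb3) count
`min(copies per member)`: all members must be present for one complex.
The microaerophily flag is true iff at least one high-affinity cytochrome
complex is complete. The fermentation panel's KO sets are a documented
curation (the end products are standard; no canonical gene list exists).

## Machinery adjudication

Detection records from a scanner (TXSScan/ConjScan digest) and a BRITE
screen are unioned per system copy. Missing mandatory roles may be filled
by an externally supplied homology rescue table; rescue is input, not
computed, because homology search is out of scope — what the package
computes is the neighbourhood filter (candidate ranks within a ±10-gene
window of the cluster, truncated on linear replicons, wrapped on circular
ones; window and topology configurable, defaulting to linear for
contig/scaffold assemblies and circular for chromosome-level ones).

Status and provenance code: scanner-complete → `complete_scan_confirmed`
(a); scanner-incomplete but union with BRITE complete →
`complete_brite_only` (f); union incomplete but rescue fills the gaps →
`complete_after_rescue` (c when the scanner was ConjScan, e otherwise);
otherwise `highly_incomplete` (b) when the missing fraction exceeds 1/3,
else `incomplete` (d). The 1/3 threshold is a package choice consistent
with reported cases labelling 6-of-13-missing systems highly incomplete;
it is configurable per model. Published code letters are not fully
consistent across reports (the same letter can mean different things in
different tables); this package fixes the secretion-system scheme above
and records the scanner on every status. A scanner-complete system whose
BRITE screen disagrees is still complete with code a — the scanner is the
primary detector — with the disagreement recoverable from the detection
records. Model role lists (13 T2SS genes, 17 T4SS_G genes, etc.) ship as
editable YAML following MacSyFinder-style definitions.

## CAZymes

Family tokens collapse subfamily and coordinate decorations (GH5_25,
GH18(23-214) → GH5, GH18); multi-domain assignments (GH18+CBM5) count
each family once. The polymer map is config; GH18→chitin, GH5→cellulose
and GH2→xylan anchor the shipped default and the remaining assignments
follow the common CAZy-based polymer scheme as a marked curation.
Families absent from the map are reported under `unmapped`, never
silently dropped, and zero rows are retained as explicit absences.

## Species delineation

Edges require ANI > 95 *and* dDDH > 70 by default — strict inequality,
matching the "exceeds the threshold" convention; `strict=False` and
`combine_rule="either"` are available. Clusters are connected components,
so conspecificity is transitively closed; because a component need not be
a clique, the per-pair pass/fail table is part of the result and flags
genomes linked into a cluster despite failing a threshold with some
member. No genus-level cutoff is attempted.

## Synthetic data

The generator emulates the statistical structure the scoring assumes, not
real genomes: per-category counts are Poisson draws with mean =
(archetype-dependent landmark multiple) × genome size, where planted
copiotrophs sit 60% beyond the copiotroph landmark in the copiotrophic
direction (mirrored for oligotrophs) and the `moderate` archetype places
65% of categories on the copiotroph side with the rest mid-range —
approximating a 21-of-33 majority. Background genes draw only COG letters
outside the scored landmark set, so the planted per-category structure is
not perturbed; ~4% of genes are left unassigned to populate the `unknown`
category. Default genome size 4.5 Mb and ~3000 background genes give
ORF totals in the low thousands, the realistic order for the 4–5 Mb
marine heterotroph genomes this pipeline targets. Similarity matrices are
block-constant plus Gaussian noise, clipped to [0, 100]. Each genome's
RNG stream derives from (seed, CRC32 of genome id), so cohorts are
reproducible gene-for-gene and adding a genome does not perturb others.

What passing synthetic tests shows: the scoring, adjudication and
clustering rules behave as specified under their own generative
assumptions. What it does not show: robustness to annotation-tool
version drift, mis-annotation, overdispersed gene counts (a
negative-binomial option exists but defaults off), or biased landmark
values — real-genome results depend on those inputs.

## Problem sizes and determinism

Recovery experiments use 20 seeded replicates (single genomes for
archetype recovery; 6-genome, 2-block cohorts for species recovery) and
the exhaustive machinery oracle covers all role patterns for models of up
to 6 roles; these sizes exercise every rule branch while keeping the full
suite under half a minute. All randomness flows through explicit seeds;
reports are byte-identical across reruns on identical inputs.

## Known limitations

* Landmark reference values and the published SAP KO curation are not
  shipped; real-genome trophic scores and SAP values require the user to
  supply them.
* Role→KO maps, panel KO ids and machinery role lists are curations;
  organisms using non-orthologous replacements will under-call
  completeness.
* Rank-based neighbourhoods ignore contig boundaries on fragmented
  assemblies.
* The per-pair decision table exposes, but the clustering does not
  resolve, non-transitive similarity structures.
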