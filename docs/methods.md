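# Methods

## The model

A variant is **causative** when it is both pathogenic (molecularly
damaging) and involved in producing the patient's phenotypes. `phenovar`
estimates `P(causative | variant, profile)` with a random forest over a
60-feature representation and ranks the filtered variants of a VCF by
that probability. The three evidence channels are kept deliberately
separable: molecular evidence enters only through three per-variant
pathogenicity scores, phenotypic evidence only through the ontology-based
similarity and the high-level phenotype flags, and inheritance evidence
through zygosity and mode-of-inheritance (MOI) features plus hard
filters.

### Phenotype ontology construction

Phenotype vocabularies describe the same biology with different classes
across species. The integration device is the *phene pattern*: every
phenotype class `P` is reformulated as

    P EquivalentTo: has-part some (E and has-quality some Q)

with `E` an entity (anatomical structure or biological process) and `Q` a
quality. Raw definitional axioms are rewritten conjunct-by-conjunct,
left-to-right, starting from `E = Q = owl:Thing`:

| conjunct | effect |
|---|---|
| `inheres-in X` | `E ≔ X` |
| `inheres-in-part-of X` | `E ≔ part-of some X` |
| `modifier X` | attach `modifier X` to `Q` |
| `has-quality X` | sets `Q` while `Q` is still the top class (the genus quality); later occurrences attach to `E` |
| `towards / exists-during / part-of / has-central-participant / results-from / occurs-in X` | attach to `E` |
| `has-part X1 … Xn` | intersection of recursively rewritten sub-definitions |

Two design points deserve note. First, replacement rules (`E ≔ X`)
overwrite qualifiers attached earlier; the input order of conjuncts is
therefore semantically relevant, and the readers preserve row order.
Second, the genus-quality reading of the first `has-quality` conjunct is
what lets flat (relation, filler) conjunct lists express definitions
whose top-level class is the quality itself.

For each distinct entity expression `E` an abstract class
`S ≡ has-part some (part-of some E)` is generated with a deterministic
content-hashed ID, so that a phenotype of any *part* of `E` is subsumed
by `S`: the phenotype hierarchy inherits the part-of structure of the
anatomy. Zebrafish annotations, which use entity and quality classes
directly, become one generated class per unique `(E1, Q[, E2])`
combination, with a second entity attached to the quality as
`towards E2`. Disjointness axioms in source ontologies are dropped at
parse time (they only produce spurious inconsistencies under the
rewriting).

### The restricted reasoner

Instead of a general OWL 2 EL reasoner, subsumption is decided for
exactly the fragment the rewriting produces. `P1 = (E1, Q1)` is subsumed
by `P2 = (E2, Q2)` iff

* **entity condition** — `E2` reaches `E1` under the reflexive-transitive
  closure of is-a edges; when `E2` is part-of-wrapped (S-classes,
  `inheres-in-part-of`), the closure of is-a ∪ part-of is used instead;
* **quality condition** — `Q2` reaches `Q1` under quality is-a closure;
* **qualifier compatibility** — every qualifier conjunct of the parent
  (modifier, towards, …) is matched by a child qualifier of the same
  relation whose filler it subsumes; qualifiers absent from the parent
  impose nothing. Consequently an unmodified quality subsumes its
  modified refinements.

Intersections use the sufficient rule: every parent atom must subsume
some child atom. Classes with mutual subsumption are quotiented into
equivalence groups (canonical representative = lexicographically smallest
ID, the hierarchy root forced canonical for its group) so the stored edge
set is a transitive reduction of a DAG, while closure queries expand the
groups in both directions. The whole relation is verified against an
independent brute-force pairwise oracle on randomized instances in the
test suite.

Open semantic points — how modifier axes interact during subsumption and
what inferential role `exists-during`-style qualifiers play — are not
settled by the phene pattern itself; the choices above (parent-absent-or-
subsuming; attach-but-inert beyond matching) are the package's own and
are exercised explicitly by tests.

### Similarity

Information content is annotation-frequency based: annotations propagate
to all ancestors (true-path rule) and `IC(c) = −ln(n_c / N)` in nats,
with `N` the number of annotated genes. Classes with no annotated gene
receive the corpus minimum frequency `1/N` rather than infinite IC, so
Resnik similarity — `max IC` over common ancestors, both arguments
included among their own ancestors — is always finite. Profile-vs-gene
similarity is the symmetric best-matching average

    BMA(p, g) = ½ ( mean_{x∈p} max_{y∈g} sim(x,y) + mean_{y∈g} max_{x∈p} sim(x,y) )

and per-profile scores are normalized by the profile maximum over genes
(an all-zero profile maps to all zeros). A gene's annotations are pooled
across species within the active source configuration; the three
configurations — human-derived only, model-organism only, or both — are
applied *before* normalization, so each configuration has its own
per-profile maximum.

### Features and classifier

The 60-feature layout is fixed: `score_1..3` (three pathogenicity
sources; NaN when unscored), `zygosity` (het 0 / hom 1), `moi` (Dominant
0, Recessive 1, X-linked 2, Other 3; one categorical feature, which is
the only reading consistent with the stated total of 60), 54 binary
high-level phenotype flags (flag k fires iff any profile class is
subsumed by the k-th panel class), and the normalized similarity of the
variant's gene. The panel is configuration; for synthetic worlds it is
derived breadth-first from the hierarchy root's children and padded with
the root when the hierarchy is small — padded entries are constant
features and inert for the forest. Non-exonic variants use the closest
gene by genomic distance (containment first, smallest-start tie-break).

Training examples come from a ClinVar-style labeled table. Pathogenic
variants are genotype-expanded by their disease's MOI (recessive → one
homozygote; otherwise het + hom) and paired with their own disease's
phenotypes (positives) and with a uniformly sampled *different* disease's
phenotypes (pathogenic non-causative negatives); benign variants pair
with a random disease (benign negatives). Three regimes — pathogenic-only
negatives, benign-only, and a 50/50 mix with the larger pool subsampled —
yield models that emphasize phenotype similarity, pathogenicity scores,
or a balance; the test suite asserts this emphasis asymmetry on probe
grids. Diseases without phenotype annotations cannot supply a profile and
are excluded from training.

The classifier is a 100-tree random forest, unlimited depth, 6 candidate
features per split, with the fraction-of-trees probability as the ranking
score. Missing values are imputed by label-conditional median (numeric) /
mode (categorical) at fit time; at prediction time labels are unknown, so
pooled (label-free) fill values stored on the model are applied — a
transparent approximation of decision-tree-internal fractional
imputation that keeps train/predict symmetry inspectable.

### Filtering and ranking

Per variant, in order: uncalled genotypes are removed (including
multi-allelic calls such as 1/2 that are neither `0/i` nor `i/i` for the
split allele); under recessive MOI heterozygotes are removed; variants
with *known* MAF above the cutoff (default 1%) are removed — missing MAF
is treated as rare, since novel variants absent from reference panels are
the method's main target. X-linked MOI applies no extra zygosity filter.
Nothing is ever dropped for missing pathogenicity scores; they are
imputed. Ties in probability break by higher mean of available scores,
then chromosome, position, and alleles, making top-k metrics
deterministic.

## The synthetic world

`generate_toy_world` emulates the study's resources at desk scale: a
leveled random entity DAG (default 24 entities, depth 4, part-of
probability 0.35) plus a two-level quality tree (8 base qualities, every
second one with a "severe" child); two phenotype classes per entity via
the rewrite rules (~50 concrete classes plus S-classes); 30 genes whose
annotation sets partition the concrete classes (disjoint "themes", so a
disease profile identifies its gene); 20 diseases, each drawing 4
phenotypes from one designated causal gene's annotations, with MOI
sampled 40/35/10/15% over Dominant/Recessive/X-linked/Other; annotation
source tags sampled 50/30/20% human/mouse/zebrafish with a 30% chance of
a second species; genes laid out on one chromosome as 10 kb intervals
with 10 kb gaps.

Spike-in cases place `background_n` benign variants uniformly over genes
(probability `fraction_exonic`, default 0.9) or intergenic space — 49%
het / 49% hom / 2% uncalled; MAF 25% common (uniform 0.02–0.5), 60% rare
(< 0.009), 15% missing — and insert exactly one causative variant in the
disease's causal gene (homozygous if recessive), with missing MAF.

The score signal model is parametric: benign scores ~ Normal(0.3, σ),
pathogenic ~ Normal(0.8, σ), truncated to [0, 1]. `separable` uses σ =
0.05 with clipping to disjoint ranges ([0, 0.55] vs [0.6, 1.0]), so
causative scores strictly exceed all background scores; `noisy` overlaps
the two distributions at a configurable σ. A similarity-decay parameter
removes a fraction of each causal gene's annotations before corpus
construction. Truth metadata (case → causative variant key and causal
gene) is kept out of every pipeline-visible file.

What this surrogate does **not** emulate: real allele-frequency spectra
and linkage structure, realistic exome variant counts (hundreds of
background variants stand in for tens of thousands), indels and
multi-nucleotide variants in the generator, overlapping gene annotations
in the corpus, and the weak cross-species noise of real orthology
mapping. Passing tests therefore demonstrate the *mechanics* and the
*qualitative behavior* of the method — not clinical-scale accuracy.

## Experiment design and problem sizes

The evaluation experiments mirror the study's noise analyses, at sizes
chosen as the package's desk-scale defaults:

* **clean recovery** — 200 spike-in cases × 500 background variants,
  separable signal, model trained (mixed regime) on a *disjoint* world so
  no panel, corpus or score table is shared with evaluation;
* **co-morbidity / dropout** — 80 cases × 300 background variants, paired
  across conditions on one seeded cohort; co-morbidity unions in a second
  disease's phenotypes, dropout removes each profile class with
  probability 1/3 (resampling so a profile never empties);
* **two-variant discrimination** — 100 cases; a second causative variant
  for the most BMA-similar other disease is spiked in and both variants'
  ranks recorded while the profile matches the first;
* **IC–rank correlation** — 80 cases with dropout probability rising
  linearly from 0 to 0.85 with case index; Spearman ρ between summed
  profile IC and causative rank. Profile IC sums class ICs with no
  redundancy correction, and uses corpus IC only (a mixed depth/frequency
  measure would need an unspecified combination rule).

The noise experiments run under the noisy signal model (σ = 0.3): under
fully separable scores the ranking is insensitive to phenotype
perturbation (recovery stays at 100% in every condition), which would
make the degradation comparisons vacuous and the correlation undefined on
constant ranks. This is an experiment-design choice, not a claim about
real data.

## Numerical and degenerate-input choices

* Natural log for IC; normalization removes the scale downstream.
* Zero-maximum profiles normalize to all zeros (no division by zero).
* Recovery percentages divide by the number of cases whose causative
  variant received a rank; unranked cases are reported separately.
  Median rank is the lower median.
* ROC AUC follows the pairwise-comparison estimator with ties counted ½
  (checked against a brute-force implementation).
* Empty VCFs/rank inputs yield empty results with a warning, not errors;
  profile classes absent from the hierarchy, unknown relations,
  unresolvable fillers, unknown table columns and multi-sample VCFs are
  hard errors naming the offender.
* Generated class IDs are content hashes of normalized definitions, so
  repeated builds are bit-identical; all stochastic steps take explicit
  seeds and the end-to-end pipeline is byte-deterministic.

## Known limitations

The reasoner covers only the phene-pattern fragment (no general OWL
semantics, no consistency checking). Compound heterozygotes, trio
analysis and structural variants are out of scope. The C4.5-style
imputation is approximated as described above. The 54-class panel for
real ontologies must be supplied by configuration. Probabilities are
uncalibrated scores — ranks, not risks.
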