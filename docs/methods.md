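# Methods

## The network model

A network couples two node sets — organisms and chemical compounds —
through signed associations `(organism, compound, activity, sign)` with
literature reference keys. Activities are `import` and `export` (transport
of a small molecule) and `degradation` (breakdown of a macromolecule).
Negative associations record curated evidence of *absence* of a transport
or degradation capability; they share the same record shape and are kept
distinct from mere missingness. Invariants enforced by `validate_network`:
every microbe carries an NCBI taxid, `(name, rank)` is unique per side,
transport applies only to small molecules and degradation only to
macromolecules, `(organism, compound, activity)` is unique, and no key
carries both signs. Violations are reported (deterministically ordered),
never raised, so a curator can see all problems at once.

Three construction operations, all pure:

* **Strain consolidation** replaces all strain-rank organisms of one
  species (identified by `lineage["species"]`) with a single species
  record holding the union of their associations. Duplicate contributions
  merge their reference lists; opposite-sign contributions raise a
  `ConflictError` rather than being resolved silently, because there is no
  principled automatic resolution for contradictory strain evidence. The
  consolidated species inherits the smallest strain taxid — an arbitrary
  but deterministic choice, recorded here because any choice is a proxy
  for the species-level taxid the curator should supply.
* **Degradation propagation** makes every positive degrader of a
  macromolecule an exporter of each of its degradation products, with
  provenance `indirect_degradation`. Existing direct exports are left
  untouched; negative degradation records propagate nothing. The operation
  is idempotent, never removes records, and never changes a sign.
* **Merging** unifies organisms on NCBI taxid (fallback `(name, rank)`)
  and compounds on KEGG id (fallback name), unions associations with
  de-duplication, and renumbers colliding reference keys in stable order
  of citation text. Merge with the empty network is the identity and the
  merged association set is independent of argument order.

## JSON dialect and tables

The four-file JSON dialect mirrors deposited resources of this kind: a
network file of association objects with keys `"Species"`,
`"Small-molecule metabolite or macromolecule"`, `"Metabolic activity"` and
`"Ref. #"` (exact spellings, trailing `#` included) plus an `"ID"`, and
three side files annotating organisms (NCBI taxid, rank, lineage),
compounds (KEGG id, class, degradation products) and references. Because
the controlled vocabulary of activity tokens in the wild is not fixed,
readers accept a YAML *dialect map* of alias → canonical token; the
canonical set is `{import, export, degradation}` with a `not-` prefix for
negative associations. Generated ids use a reserved `GEN_#####` namespace
so synthetic records can never collide with deposited `NJC19_#####` ids.

Writers sort objects by id/name and dump with sorted keys, so output is
byte-reproducible; the JSON round trip preserves the association multiset
exactly, including provenance (an optional `"Provenance"` key is written
only for indirect records). The flat association table carries the four
canonical columns plus the id; provenance is not representable there, so
the table round trip is exact up to provenance (exact on un-propagated
networks).

Abundance tables are samples × taxa TSV with `group` (and optional
`study`) columns; percent-convention inputs (row sums ≈ 100) are detected
via the median row sum and rescaled to fractions with a logged warning.
Metabolite tables are replicates × metabolites TSV; a pseudo-row labelled
`host_or_diet_derived` carries per-metabolite 0/1 flags.

## Species selection

A species passes the prevalence filter when it is detected (relative
abundance ≥ `abundance_min`, default 10⁻⁵) in at least `prevalence_min`
(default 0.90) of the samples — within each study when a study column is
present, a species qualifying if it passes in *any* study, since each
study contributes its own list before pooling. Both thresholds are
inclusive. The genus-coverage summary weights samples equally (not by
study) and uses the sample standard deviation (n − 1 denominator); the
genus of a taxon defaults to the first token of its binomial name unless
an explicit genus map is given.

## Degree statistics and fits

Degrees count **distinct** small molecules (organism side) or organisms
(compound side) joined by a *positive* transport association of one
direction; degradation links, negative records and duplicate evidence
lines never contribute. Host cells are excluded unless requested, so the
statistics are per microbial species. Organism-side means include
zero-degree species — the full species catalogue is the divisor for
fractions such as "imported by 36% of species" — while compound-side
means are taken over compounds with at least one link of the direction
(flagged `mean_over_linked` in the output), since a mean over never-
transported compounds is not meaningful. Edge-count conservation
(Σ organism degrees = Σ compound degrees per direction) holds by
construction and is asserted in the tests, including after degradation
propagation.

Both fits are discrete maximum likelihood with `k_min = 1` by default
(both laws are degenerate or undefined at k = 0); the `method` field of
every `FitResult` records the procedure.

* Exponential: on support k ≥ k_min the law is geometric,
  P(k) = (1 − e^(−r)) e^(−r(k − k_min)), with closed-form MLE
  r̂ = ln(1 + 1/(k̄ − k_min)). A sample entirely at k_min raises
  `DegenerateError` (the rate diverges).
* Power law: P(k) = k^(−γ) / H(γ; k_min, k_max) with
  H = Σ_{k=k_min}^{k_max} k^(−γ). Truncation is mandatory because γ < 2
  is non-normalizable on infinite support; `k_max` defaults to the largest
  observed degree. The likelihood is maximised by bounded scalar search on
  γ ∈ (10⁻³, 20) to well below 10⁻⁶ tolerance; the tests pin the optimum
  against an independent dense grid search.

No model selection is performed: the functional forms are asserted inputs
and only their parameters are estimated.

## Concordance validation

Producers of a metabolite are the candidate-pool taxa with a positive
export link (species rank) or, at genus rank, the genera in which a strict
majority (> 50%) of the network's species export it; consumers use import
links symmetrically. Producer sets should be computed on a
degradation-propagated network. Candidate metabolites must be network
compounds, not flagged host/diet-derived, and both the metabolite
group-mean concentration and the producer-set group-mean abundance must
span at least `min_fold` (default 1.5) across groups; an optional check
flags metabolites whose total consumer abundance falls below half the
producer abundance.

For each ordered group pair (i, j), i before j in the declared group
order, `f = mean_j / mean_i` of the producer-set summed abundance
(replicate means) and `g` analogously for the concentration. A record
*matches* when (f − 1)(g − 1) > 0; ties (f = 1 or g = 1) are excluded from
the match rate. Pairs with a zero group mean are excluded and logged — a
pseudocount would manufacture fold changes.

The permutation test re-assigns producers uniformly at random without
replacement, keeping set sizes (and hence the total producer count) equal
to the observed ones. By default each metabolite draws from its own
candidate pool (`pool_mode="per_source"`); a `global` mode partitions one
pooled draw into the observed per-metabolite counts, for study designs
where sources share one pool. A draw succeeds when f′ ≥ f for every pair
with f, g both ≥ 1 and f′ ≤ f for every pair with both ≤ 1 (non-strict
comparisons). The reported P value is the add-one estimator
(b + 1)/(N + 1), never exactly zero, with the raw success proportion also
reported.

**Calibration caveat.** The success event is a *conjunction* over all
qualifying pairs. With a single potential qualifying record the P value is
exactly uniform under the null: qualification (sign(log f) = sign(log g))
has probability ½ independent of |log f| when groups are exchangeable, and
this exactly cancels the conditional halving of the p-range, giving
P(p ≤ α) = α. With several independent qualifying records the conjunction
makes small P values likelier than α under the null — a property of the
test's published design, not of this implementation. The calibration
simulations therefore use minimal study units (two groups, one measured
metabolite); multi-record P values should be read as descriptive evidence
rather than exact tail probabilities.

## Synthetic-data generators

`gen_network` plants both degree laws. Organism degrees are geometric
draws (r = 0.2 import, 0.3 export by default), with 5% of species set to
degree zero per direction — detected communities always include members
without curated transport evidence, and the fits exclude zeros regardless.
Compound target degrees are power-law draws (γ = 1.4). Two independent
marginals cannot generally be realised jointly, so the compound side is
reconciled to the organism stub total in two steps: the truncation cutoff
is chosen so the expected compound total matches the organism total, and
the residual is absorbed multiplicatively by the tail (degrees ≥ 10) with
largest-remainder rounding — a power law is scale-invariant, so
proportional tail rescaling preserves the exponent, whereas spreading unit
corrections over the head would visibly distort it. Edges are then placed
compound-by-compound, largest degree first, each taking the organisms with
the most remaining stubs (greedy Gale–Ryser realisation, random
tie-breaks). Species are grouped into synthetic genera (sizes
1 + Poisson(3)) so the genus majority rule is exercisable; every
macromolecule gets a degradation rule (1–5 products) and 1 + Poisson(2)
degraders; negative associations are added on free key slots at one tenth
of the positive count.

`gen_experiment` draws taxon abundances as
exp(base + group shift + replicate noise), normalised per sample, with
base ~ N(0, 1), group shifts ~ N(0, 2²) on the natural-log scale — the
magnitude of antibiotic- or diet-scale perturbations, the regime the
1.5-fold candidate filter targets — and replicate noise N(0, 0.1²).
Profiles are i.i.d. across taxa, which makes observed producer sets
exchangeable with random same-size sets: the symmetry the permutation
calibration relies on. Each measured metabolite's group level is
baseline × (producer-set replicate-mean abundance)^β, with per-replicate
lognormal noise of s.d. σ (default 0.2); with β = 1 and σ = 0, g = f
exactly, by construction. `gen_null_experiment` draws group levels
independently of the microbiome. Default design: 3 groups × 5 replicates,
10 measured metabolites, 10% flagged host/diet-derived.

What the generators deliberately do not emulate: real phylogenetic
composition, compositional correlation structure between taxa,
measurement-specific metabolomics error models, or per-study sequencing
depth effects. Passing tests on these synthetics therefore demonstrate
correctness of the algorithms and calibration of the permutation machinery
under the stated model, not performance on any particular real dataset.

## Problem sizes in the test suite

The suite exercises full published scale (838 species) where cheap —
network generation, degree fits, catalogue round trips — and 20–60-species
networks for loops over many seeds (50 round-trip networks, 100
match-rate calibration studies, 200 null-calibration studies at
n_perm = 199). The calibrated match-rate summary frozen in the tests
(median > 0.9, minimum ≥ 0.75 across the 100 seeded studies at β = 1,
σ = 0.2) comes from running exactly that simulation; it is a regression
anchor for the generator-plus-pipeline pair, not an external truth.

## Known limitations

* Strain consolidation requires `lineage["species"]` on every strain and
  offers no automatic resolution of contradictory strain evidence.
* The association-table form cannot carry provenance; only the JSON
  dialect round-trips it.
* The greedy edge placement realises the degree sequences "as closely as
  feasible"; when a compound's target degree exceeds the number of
  organisms with remaining stubs, its realised degree is smaller.
* Multi-record permutation P values are anti-conservative under the null
  (see the calibration caveat above).
* `fit_powerlaw`'s default `k_max` (largest observed degree) slightly
  underestimates the true truncation point of sparse samples; pass the
  known support explicitly when available.
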