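# gutnet

Tools for literature-curated, bipartite **gut microbiota–metabolite
interaction networks**: organisms (microbial species and a few host cell
types) linked to chemical compounds through signed, referenced metabolic
associations — small-molecule **import**/**export** and macromolecule
**degradation**, plus curated *negative* associations recording that an
organism cannot transport or degrade a compound.

The package is aimed at microbiome researchers who want to (1) build and
curate such networks from association tables or the four-file JSON dialect
used by deposited resources of this kind, (2) characterise their bipartite
topology, and (3) test whether a network's producer annotations are
consistent with paired microbiome/metabolome measurements.

## What it computes

**Network construction.** Strain-level records are consolidated into
species (union of associations, reference merging, sign-conflict
detection); every species that degrades a macromolecule becomes an
*indirect exporter* of that macromolecule's degradation products; two
networks are merged through shared NCBI taxids and KEGG compound ids.
A validator reports every schema violation deterministically.

**Species selection.** From metagenome relative-abundance tables, the
prevalence filter keeps species detected (abundance ≥ 0.001%) in ≥ 90% of
a study's samples, and a genus-coverage summary reports which fraction of
total abundance the selected genera represent.

**Degree distributions.** Organism-side transport degrees are fitted with
the discrete exponential (geometric) law *P(k) ∝ e^(−rk)* on *k ≥ k_min*
(closed-form MLE, *r̂ = ln(1 + 1/(k̄ − k_min))*); compound-side degrees with
the truncated discrete power law *P(k) ∝ k^(−γ)* on *[k_min, k_max]*
(numerical MLE with the generalized harmonic normalizer).

**Concordance validation.** For each metabolite with producers in the
network, fold changes between experimental groups *i → j* are computed for
the summed producer abundance (*f_ij*) and the metabolite concentration
(*g_ij*); the match rate is the fraction of pairs with concordant
direction, and a permutation test re-assigns producers uniformly at random
(matched set sizes) to ask how often random sets satisfy *f′_ij ≥ f_ij*
for all pairs with *f, g ≥ 1* and *f′_ij ≤ f_ij* for all pairs with
*f, g ≤ 1*; *P = (successes + 1)/(n_perm + 1)*. At genus rank a genus
counts as producer when a strict majority (> 50%) of its species in the
network export the metabolite.

**Synthetic data.** Seeded generators produce networks with planted
exponential/power-law degree laws at the published scale (838 species,
266 + 17 compounds) and paired abundance/metabolite experiments with a
planted producer → metabolite dependence (*level ∝ abundance^β*, lognormal
noise) or a null without it — so the whole pipeline is testable without
downloads.

## Worked example

```python
from gutnet import (NetworkGenParams, ExperimentDesign, gen_network,
                    gen_experiment, propagate_degradation, organism_degrees,
                    compound_degrees, fit_exponential, fit_powerlaw,
                    degree_summary, run_validation)

net = propagate_degradation(gen_network(NetworkGenParams(seed=7)))
summ = degree_summary(net)
print(f"species: {summ['n_species']}, "
      f"mean imports: {summ['organism']['import']['mean']:.1f}, "
      f"mean exports: {summ['organism']['export']['mean']:.1f}")
r = fit_exponential(organism_degrees(net, "import"))
g = fit_powerlaw(compound_degrees(net, "import"))
print(f"organism import degrees: r = {r.param:.2f} (n={r.n_used})")
print(f"compound import degrees: gamma = {g.param:.2f} (n={g.n_used})")

small = propagate_degradation(gen_network(NetworkGenParams(
    n_species=40, n_metabolites=15, n_macromolecules=2, seed=3)))
ab, mb, truth = gen_experiment(small, ExperimentDesign(beta=1.0, sigma=0.2,
                                                       seed=5))
res = run_validation(small, ab, mb, n_perm=9999, seed=1)
print(f"candidates: {len(set(r.metabolite for r in res.records))}, "
      f"match rate: {res.match_rate:.3f}, "
      f"P = {res.p_value:.4f} ({res.n_qualifying_pairs} qualifying pairs)")
```

prints

```
species: 838, mean imports: 5.3, mean exports: 3.7
organism import degrees: r = 0.20 (n=796)
compound import degrees: gamma = 1.41 (n=266)
candidates: 5, match rate: 1.000, P = 0.0001 (15 qualifying pairs)
```

The first block generates a full-scale network, propagates degradation
products, and recovers the planted degree-law parameters (r = 0.2,
γ = 1.4) from the realised degree sequences. The second block runs the
validation pipeline on a small planted experiment: with β = 1 and moderate
noise every qualifying fold-change pair is concordant (match rate 1.000)
and random producer sets almost never reproduce the observed fold changes
(P ≈ 10⁻⁴, the resolution floor of 9,999 permutations).

A `gutnet` CLI wraps the same functions: `gutnet simulate network`,
`gutnet simulate experiment`, `gutnet convert`, `gutnet select`,
`gutnet stats`, and `gutnet validate` (see `--help` on each).

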