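"""Seeded generators emulating the study inputs.

``gen_network`` builds an organism–compound network whose organism-side
transport degrees follow a geometric (discrete exponential) law and whose
compound-side degrees follow a truncated discrete power law, at the scale
of the published resource (838 species, 266 small molecules, 17
macromolecules, r ≈ 0.2/0.3, γ ≈ 1.4). ``gen_experiment`` pairs a taxon
abundance table with a metabolite table in which each metabolite tracks the
abundance of its network producers through a planted power relation
``level ∝ (producer abundance)^β`` with multiplicative lognormal noise;
``gen_null_experiment`` draws metabolite levels independently of the
microbiome, for calibration of the permutation test.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream per
call, so every artifact is reproducible bit-for-bit given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import producers_of
from .errors import InfeasibleDegreeError
from .io import AbundanceTable, MetaboliteTable
from .model import (Association, Compound, DegradationRule, Network, Organism)

PHYLA = ("Bacillota", "Bacteroidota", "Pseudomonadota", "Actinomycetota",
         "Verrucomicrobiota")


@dataclass
class NetworkGenParams:
    """Scale and degree-law parameters of the generated network.

    Defaults mirror the published resource: 838 microbial species, 266
    small molecules plus 17 macromolecules, exponential organism degrees
    with rates 0.2 (import) and 0.3 (export), power-law compound degrees
    with exponent 1.4, and roughly one negative association per ten
    positive ones. ``zero_fraction`` is the share of species left without
    links in a given direction (degree-law fits exclude zeros anyway).
    """

    n_species: int = 838
    n_metabolites: int = 266
    n_macromolecules: int = 17
    r_import: float = 0.2
    r_export: float = 0.3
    gamma: float = 1.4
    neg_fraction: float = 0.1
    zero_fraction: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_species, self.n_metabolites, self.n_macromolecules) <= 0:
            raise ValueError("counts must be positive")
        if min(self.r_import, self.r_export, self.gamma) <= 0:
            raise ValueError("rates and exponent must be positive")
        if not (0 <= self.neg_fraction < 1 and 0 <= self.zero_fraction < 1):
            raise ValueError("fractions must be in [0, 1)")


@dataclass
class ExperimentDesign:
    """Shape and planted structure of a paired microbiome/metabolome study.

    ``beta`` links metabolite level to producer-set abundance
    (level ∝ abundance^β); ``sigma`` is the lognormal s.d. of replicate
    noise on metabolite concentrations; ``group_effect_sd`` is the
    lognormal s.d. (natural-log scale) of per-group taxon abundance shifts,
    sized for strong perturbations such as antibiotic treatment or diet
    switches — the regime the 1.5-fold candidate filter targets.
    """

    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("I", 5), ("II", 5), ("III", 5)])
    rank: str = "species"
    beta: float = 1.0
    sigma: float = 0.2
    n_metabolites_measured: int = 10
    host_derived_fraction: float = 0.1
    group_effect_sd: float = 2.0
    replicate_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if any(n < 1 for _, n in self.groups):
            raise ValueError("replicate counts must be >= 1")
        if self.sigma < 0 or self.beta < 0:
            raise ValueError("beta and sigma must be nonnegative")


# ---------------------------------------------------------------------------
# samplers (also used as fitting oracles' counterparts)
# ---------------------------------------------------------------------------

def sample_geometric(r: float, n: int, rng: np.random.Generator,
                     k_min: int = 1) -> np.ndarray:
    """Draws from P(k) ∝ e^(−rk) on k >= k_min (shifted geometric)."""
    return k_min - 1 + rng.geometric(p=1.0 - np.exp(-r), size=n)


def sample_truncated_powerlaw(gamma: float, k_min: int, k_max: int, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from P(k) ∝ k^(−γ) on [k_min, k_max]."""
    support = np.arange(k_min, k_max + 1, dtype=float)
    pmf = support ** (-gamma)
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random(n)
    return k_min + np.searchsorted(cdf, u, side="left")


def _truncated_powerlaw_mean(gamma: float, k_min: int, k_max: int) -> float:
    support = np.arange(k_min, k_max + 1, dtype=float)
    w = support ** (-gamma)
    return float((support * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def _reconcile_totals(comp_deg: np.ndarray, target_total: int,
                      k_cap: int) -> np.ndarray:
    """Adjust compound degrees so their sum hits the organism stub total.

    The residual is absorbed multiplicatively by the tail (degrees >= 10):
    a power law is scale-invariant, so proportionally rescaling large
    degrees preserves the exponent, while the head probabilities — which
    dominate the fit — stay untouched. The few units left over after
    rounding go to the largest-degree compounds.
    """
    deg = comp_deg.copy()
    diff = int(target_total - deg.sum())
    tail = np.flatnonzero(deg >= 10)
    if diff != 0 and len(tail) and deg[tail].sum() + diff > len(tail):
        scaled = deg[tail] * (1.0 + diff / deg[tail].sum())
        floors = np.maximum(np.floor(scaled).astype(int), 1)
        short = int(deg[tail].sum() + diff - floors.sum())
        if short > 0:
            order = np.argsort(-(scaled - floors), kind="stable")
            floors[order[:short]] += 1
        deg[tail] = np.minimum(floors, k_cap)
        diff = int(target_total - deg.sum())
    for idx in np.argsort(-deg, kind="stable"):
        if diff == 0:
            break
        if diff > 0:
            take = min(k_cap - int(deg[idx]), diff)
            deg[idx] += take
            diff -= take
        else:
            take = min(int(deg[idx]) - 1, -diff)
            deg[idx] -= take
            diff += take
    if diff != 0:
        raise InfeasibleDegreeError(
            "cannot reconcile compound degrees with organism stub total")
    return deg


def _match_cutoff(gamma: float, mean_target: float, k_max_limit: int) -> int:
    """Largest truncation cutoff whose power-law mean is <= mean_target."""
    lo, hi = 2, k_max_limit
    if _truncated_powerlaw_mean(gamma, 1, lo) > mean_target:
        return lo
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _truncated_powerlaw_mean(gamma, 1, mid) <= mean_target:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _assign_edges(org_deg: np.ndarray, comp_deg: np.ndarray,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Bipartite edges meeting both degree sequences as closely as feasible.

    Compounds are processed largest-degree-first; each takes the organisms
    with most remaining stubs (ties broken by a random jitter), which is
    the greedy Gale–Ryser realisation.
    """
    remaining = org_deg.astype(float).copy()
    edges: list[tuple[int, int]] = []
    for ci in np.argsort(-comp_deg, kind="stable"):
        d = int(comp_deg[ci])
        if d == 0:
            continue
        avail = np.flatnonzero(remaining > 0)
        if len(avail) < d:
            d = len(avail)
        if d == 0:
            continue
        jitter = rng.random(len(avail)) * 0.5
        pick = avail[np.argsort(-(remaining[avail] + jitter), kind="stable")[:d]]
        for oi in pick:
            edges.append((int(oi), int(ci)))
            remaining[oi] -= 1
    return edges


def gen_network(params: NetworkGenParams | None = None) -> Network:
    """Generate a network with planted organism- and compound-side degree laws.

    Species are grouped into synthetic genera (sizes 1 + Poisson(3)) so the
    genus-level majority rule is exercisable; every macromolecule receives a
    degradation rule with 1–5 small-molecule products and a handful of
    degraders. The result passes ``validate_network``.
    """
    p = params or NetworkGenParams()
    rng = np.random.default_rng(p.seed)

    # organisms with genus structure
    organisms: dict[str, Organism] = {}
    genus_idx, placed = 0, 0
    while placed < p.n_species:
        genus_idx += 1
        size = 1 + int(rng.poisson(3.0))
        phylum = PHYLA[int(rng.integers(len(PHYLA)))]
        for si in range(1, size + 1):
            if placed == p.n_species:
                break
            placed += 1
            genus = f"Simgenus{genus_idx:03d}"
            name = f"{genus} sp{si}"
            organisms[name] = Organism(
                organism_id=name, name=name, rank="species", kind="microbe",
                ncbi_taxid=1_000_000 + placed,
                lineage={"domain": "Bacteria", "phylum": phylum,
                         "genus": genus, "species": name},
                sample_sources=["synthetic"])
    org_ids = list(organisms)

    compounds: dict[str, Compound] = {}
    for i in range(1, p.n_metabolites + 1):
        name = f"metabolite_{i:03d}"
        compounds[name] = Compound(compound_id=name, name=name,
                                   klass="small_molecule",
                                   kegg_cid=f"C9{i:04d}")
    macro_names = [f"macromolecule_{i:02d}" for i in range(1, p.n_macromolecules + 1)]
    for name in macro_names:
        compounds[name] = Compound(compound_id=name, name=name,
                                   klass="macromolecule")
    small_names = [c for c in compounds if compounds[c].klass == "small_molecule"]

    references = {"1": "synthetic generator, organism-side evidence",
                  "2": "synthetic generator, compound-side evidence"}

    associations: list[Association] = []
    serial = 1

    def add(org_id, cpd_id, activity, sign, refs, provenance="direct"):
        nonlocal serial
        associations.append(Association(
            assoc_id=f"GEN_{serial:05d}", organism_id=org_id, compound_id=cpd_id,
            activity=activity, sign=sign, refs=refs, provenance=provenance))
        serial += 1

    for direction, rate in (("import", p.r_import), ("export", p.r_export)):
        org_deg = sample_geometric(rate, p.n_species, rng)
        zeros = rng.random(p.n_species) < p.zero_fraction
        org_deg[zeros] = 0
        org_deg = np.minimum(org_deg, len(small_names))
        total = int(org_deg.sum())
        k_cap = min(p.n_species, total)
        cutoff = _match_cutoff(p.gamma, total / p.n_metabolites, k_cap)
        comp_deg = sample_truncated_powerlaw(p.gamma, 1, cutoff,
                                             p.n_metabolites, rng)
        comp_deg = _reconcile_totals(comp_deg, total, k_cap)
        for oi, ci in sorted(_assign_edges(org_deg, comp_deg, rng)):
            add(org_ids[oi], small_names[ci], direction, "positive", ("1",))

    # degradation rules and degraders
    rules: list[DegradationRule] = []
    for macro in macro_names:
        n_products = 1 + int(rng.integers(5))
        products = list(rng.choice(small_names, size=n_products, replace=False))
        rules.append(DegradationRule(macro, tuple(sorted(products))))
        n_degraders = 1 + int(rng.poisson(2.0))
        degraders = rng.choice(org_ids, size=min(n_degraders, len(org_ids)),
                               replace=False)
        for org_id in sorted(degraders):
            add(org_id, macro, "degradation", "positive", ("2",))

    # negative associations on free (organism, compound, activity) slots
    n_neg = int(round(p.neg_fraction * len(associations)))
    taken = {a.key for a in associations}
    attempts = 0
    while n_neg > 0 and attempts < 50 * n_neg + 1000:
        attempts += 1
        org_id = org_ids[int(rng.integers(len(org_ids)))]
        cpd = compounds[list(compounds)[int(rng.integers(len(compounds)))]]
        activity = ("degradation" if cpd.klass == "macromolecule"
                    else ("import", "export")[int(rng.integers(2))])
        key = (org_id, cpd.compound_id, activity)
        if key in taken:
            continue
        taken.add(key)
        add(org_id, cpd.compound_id, activity, "negative", ("2",))
        n_neg -= 1

    net = Network(organisms=organisms, compounds=compounds,
                  associations=associations, degradation_rules=rules,
                  references=references,
                  metadata={"generator": "gutnet.simulate.gen_network",
                            "seed": p.seed})
    return net


# ---------------------------------------------------------------------------
# paired microbiome/metabolome experiments
# ---------------------------------------------------------------------------

def _abundance_table(taxa: list[str], design: ExperimentDesign, rank: str,
                     rng: np.random.Generator) -> AbundanceTable:
    """Lognormal compositional abundances: base x group shift x replicate noise.

    Abundance profiles are i.i.d. across taxa, which makes the observed
    producer set exchangeable with random same-size sets — the symmetry the
    permutation-test calibration relies on.
    """
    n_taxa = len(taxa)
    base = rng.normal(0.0, 1.0, size=n_taxa)
    rows, sample_ids, group_labels = [], [], []
    for group, n_rep in design.groups:
        shift = rng.normal(0.0, design.group_effect_sd, size=n_taxa)
        for rep in range(1, n_rep + 1):
            eps = rng.normal(0.0, design.replicate_sd, size=n_taxa)
            raw = np.exp(base + shift + eps)
            rows.append(raw / raw.sum())
            sample_ids.append(f"{group}_r{rep}")
            group_labels.append(group)
    data = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    return AbundanceTable(data=data, groups=pd.Series(group_labels,
                                                      index=sample_ids),
                          rank=rank, mode="relative")


def _measured_metabolites(net: Network, taxa: list[str],
                          design: ExperimentDesign,
                          rng: np.random.Generator):
    """Pick measured metabolites (those with producers in the pool) and sets."""
    eligible = []
    for cpd in sorted(net.compounds.values(), key=lambda c: c.name):
        if cpd.klass != "small_molecule":
            continue
        pset = producers_of(net, cpd.name, design.rank, taxa)
        if pset.taxa:
            eligible.append((cpd.name, pset))
    if not eligible:
        raise ValueError("network has no metabolite with producers in the pool")
    n = min(design.n_metabolites_measured, len(eligible))
    idx = sorted(rng.choice(len(eligible), size=n, replace=False))
    return [eligible[i] for i in idx]


def _experiment(net: Network, design: ExperimentDesign, null: bool):
    rng = np.random.default_rng(design.seed)
    if design.rank == "species":
        taxa = sorted(o.name for o in net.organisms.values()
                      if o.kind == "microbe" and o.rank == "species")
    elif design.rank == "genus":
        taxa = sorted({o.genus for o in net.organisms.values()
                       if o.kind == "microbe" and o.rank == "species"})
    else:
        raise ValueError("rank must be 'species' or 'genus'")

    ab = _abundance_table(taxa, design, design.rank, rng)
    chosen = _measured_metabolites(net, taxa, design, rng)
    ab_means = ab.group_means()
    group_order = [g for g, _ in design.groups]

    cols = {}
    for name, pset in chosen:
        baseline = float(np.exp(rng.normal(0.0, 1.0)))
        if null:
            group_level = {g: baseline * float(np.exp(rng.normal(0.0, 1.0)))
                           for g in group_order}
        else:
            prod = ab_means[[t for t in ab_means.columns
                             if t in pset.taxa]].sum(axis=1)
            group_level = {g: baseline * float(prod[g]) ** design.beta
                           for g in group_order}
        values = []
        for group, n_rep in design.groups:
            noise = rng.normal(0.0, design.sigma, size=n_rep) if design.sigma > 0 \
                else np.zeros(n_rep)
            values.extend(group_level[group] * np.exp(noise))
        cols[name] = values

    rep_ids, rep_groups = [], []
    for group, n_rep in design.groups:
        rep_ids.extend(f"{group}_r{i}" for i in range(1, n_rep + 1))
        rep_groups.extend([group] * n_rep)
    data = pd.DataFrame(cols, index=rep_ids)
    flags = pd.Series(rng.random(len(chosen)) < design.host_derived_fraction,
                      index=[name for name, _ in chosen])
    mb = MetaboliteTable(data=data,
                         groups=pd.Series(rep_groups, index=rep_ids),
                         host_or_diet_derived=flags, units="a.u.")
    truth = {"beta": 0.0 if null else design.beta,
             "sigma": design.sigma,
             "seed": design.seed,
             "rank": design.rank,
             "candidate_pool": taxa,
             "producer_sets": {name: sorted(pset.taxa)
                               for name, pset in chosen}}
    return ab, mb, truth


def gen_experiment(net: Network, design: ExperimentDesign | None = None):
    """Paired tables with a planted producer -> metabolite dependence.

    With ``beta=1, sigma=0`` every metabolite fold change equals its
    producer fold change exactly, by construction.
    """
    return _experiment(net, design or ExperimentDesign(), null=False)


def gen_null_experiment(net: Network, design: ExperimentDesign | None = None):
    """Paired tables with metabolite levels independent of the microbiome."""
    return _experiment(net, design or ExperimentDesign(), null=True)
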