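"""Microbiome–metabolome concordance validation with a permutation null.

For each metabolite the network names a set of microbial *producers*
(exporters) and *consumers* (importers). Where a study provides both taxon
abundances and metabolite concentrations across experimental groups, the
fold change of the summed producer abundance between groups i and j
(``f_ij``) should agree in direction with the fold change of the metabolite
concentration (``g_ij``). The overall match rate summarises that agreement,
and a permutation test asks how often producer sets of the same size drawn
uniformly at random from the observed candidate pool are at least as
concordant: a random draw *succeeds* when its fold change ``f'_ij`` is
>= f_ij for every pair with f, g both >= 1 and <= f_ij for every pair with
f, g both <= 1. The reported P value uses the add-one estimator
(successes + 1)/(n_perm + 1), so it is never exactly zero.

At species rank, producers are simply the pool members with a positive
export link. At genus rank, a genus counts as producer when a strict
majority (>50%) of its species in the network export the metabolite.
Producer sets should be computed on a degradation-propagated network so
that macromolecule degraders count as exporters of the products.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (GroupMismatchError, NoQualifyingPairsError,
                     NoRecordsError, SeedRequiredError, UnknownCompoundError)
from .io import AbundanceTable, MetaboliteTable
from .model import Network

log = logging.getLogger(__name__)


@dataclass
class ProducerSet:
    """Taxa linked to one metabolite at a given rank, within a study's pool."""

    metabolite: str
    rank: str                       # "species" | "genus"
    taxa: frozenset
    candidate_pool: frozenset
    role: str = "producer"          # "producer" | "consumer"

    def __post_init__(self):
        if not self.taxa <= self.candidate_pool:
            raise ValueError("producer taxa must be drawn from the candidate pool")


@dataclass
class FoldChangeRecord:
    """f and g for one (metabolite, ordered group pair), orientation i -> j."""

    metabolite: str
    group_i: str
    group_j: str
    f: float
    g: float

    @property
    def qualifies_up(self) -> bool:
        return self.f >= 1 and self.g >= 1

    @property
    def qualifies_down(self) -> bool:
        return self.f <= 1 and self.g <= 1

    @property
    def match(self) -> bool:
        return (self.f - 1) * (self.g - 1) > 0


@dataclass
class ConcordanceResult:
    records: list[FoldChangeRecord]
    qualifying_records: list[FoldChangeRecord]
    match_rate: float
    p_value: float
    raw_success_rate: float
    n_perm: int
    seed: int | None
    n_qualifying_pairs: int
    pool_mode: str = "per_source"
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# producer / consumer mapping
# ---------------------------------------------------------------------------

def _linked_species(net: Network, compound_id: str, activity: str) -> set[str]:
    return {a.organism_id for a in net.associations
            if a.compound_id == compound_id and a.activity == activity
            and a.sign == "positive"
            and net.organisms[a.organism_id].kind == "microbe"}


def producers_of(net: Network, metabolite: str, rank: str,
                 candidate_pool, role: str = "producer") -> ProducerSet:
    """Producers (exporters) of a metabolite among the study's taxa.

    ``candidate_pool`` holds the taxon names observed in the study at
    ``rank``. At genus rank the strict-majority rule applies: a genus is a
    producer iff >50% of that genus's species in the network export the
    metabolite.
    """
    if role not in ("producer", "consumer"):
        raise ValueError("role must be 'producer' or 'consumer'")
    activity = "export" if role == "producer" else "import"
    cpd = net.compound_by_name(metabolite)
    if cpd is None:
        raise UnknownCompoundError(f"metabolite {metabolite!r} not in the network")
    pool = frozenset(candidate_pool)
    if not pool:
        raise ValueError("candidate pool is empty")

    linked = _linked_species(net, cpd.compound_id, activity)
    if rank == "species":
        linked_names = {net.organisms[oid].name for oid in linked}
        taxa = frozenset(pool & linked_names)
    elif rank == "genus":
        by_genus: dict[str, list[str]] = {}
        for oid, org in net.organisms.items():
            if org.kind != "microbe" or org.rank != "species":
                continue
            genus = org.genus
            if genus is not None:
                by_genus.setdefault(genus, []).append(oid)
        taxa = frozenset(
            g for g in pool
            if g in by_genus
            and sum(oid in linked for oid in by_genus[g]) > 0.5 * len(by_genus[g]))
    else:
        raise ValueError(f"rank must be 'species' or 'genus', got {rank!r}")
    return ProducerSet(metabolite=metabolite, rank=rank, taxa=taxa,
                       candidate_pool=pool, role=role)


def consumers_of(net: Network, metabolite: str, rank: str,
                 candidate_pool) -> ProducerSet:
    """Consumers (importers) of a metabolite; genus rule as for producers."""
    return producers_of(net, metabolite, rank, candidate_pool, role="consumer")


# ---------------------------------------------------------------------------
# candidate filtering and fold changes
# ---------------------------------------------------------------------------

def _set_group_means(ab_means: pd.DataFrame, taxa) -> pd.Series:
    cols = [t for t in ab_means.columns if t in taxa]
    return ab_means[cols].sum(axis=1)


def select_candidates(net: Network, ab: AbundanceTable, mb: MetaboliteTable,
                      rank: str = "species", min_fold: float = 1.5,
                      check_consumers: bool = False,
                      decisions: list[str] | None = None
                      ) -> list[tuple[str, ProducerSet]]:
    """Metabolites with clear variation and their producer sets.

    Keeps a metabolite iff it is a compound of the network, is not flagged
    host/diet-derived, its max/min group-mean concentration is >= min_fold,
    and the max/min group-mean abundance of its producer set is >= min_fold.
    With ``check_consumers`` the total consumer abundance is compared
    against half the producer abundance and the outcome logged (mirrors
    dropping consumer panels when consumers are deficient).
    """
    if set(ab.group_order) != set(mb.group_order):
        raise GroupMismatchError(
            f"abundance groups {ab.group_order} != metabolite groups {mb.group_order}")
    notes = decisions if decisions is not None else []
    ab_means = ab.group_means()
    mb_means = mb.group_means()
    pool = frozenset(ab.taxa)
    kept: list[tuple[str, ProducerSet]] = []
    for metabolite in mb.metabolites:
        if net.compound_by_name(metabolite) is None:
            notes.append(f"{metabolite}: not a network compound, dropped")
            continue
        if bool(mb.host_or_diet_derived.get(metabolite, False)):
            notes.append(f"{metabolite}: host/diet-derived, dropped")
            continue
        conc = mb_means[metabolite]
        if conc.min() <= 0:
            notes.append(f"{metabolite}: zero group-mean concentration, dropped")
            continue
        if conc.max() / conc.min() < min_fold:
            notes.append(f"{metabolite}: concentration varies "
                         f"{conc.max() / conc.min():.2f}x < {min_fold}x, dropped")
            continue
        pset = producers_of(net, metabolite, rank, pool)
        if not pset.taxa:
            notes.append(f"{metabolite}: no producers in the pool, dropped")
            continue
        prod = _set_group_means(ab_means, pset.taxa)
        if prod.min() <= 0:
            notes.append(f"{metabolite}: zero producer abundance, dropped")
            continue
        if prod.max() / prod.min() < min_fold:
            notes.append(f"{metabolite}: producers vary "
                         f"{prod.max() / prod.min():.2f}x < {min_fold}x, dropped")
            continue
        if check_consumers:
            cset = consumers_of(net, metabolite, rank, pool)
            cons_total = float(_set_group_means(ab_means, cset.taxa).sum())
            prod_total = float(prod.sum())
            if cons_total < 0.5 * prod_total:
                notes.append(f"{metabolite}: consumers ({cons_total:.3g}) below "
                             f"half of producers ({prod_total:.3g}); consumer "
                             "analysis skipped")
        kept.append((metabolite, pset))
    return kept


def fold_changes(ab: AbundanceTable, mb: MetaboliteTable,
                 producer_set: ProducerSet,
                 group_pairs: list[tuple[str, str]] | None = None,
                 decisions: list[str] | None = None) -> list[FoldChangeRecord]:
    """f and g for each ordered group pair, orientation i -> j.

    f = (group-j replicate-mean producer-set abundance) /
        (group-i replicate-mean producer-set abundance); g analogous for the
    metabolite concentration. Pairs with a zero mean on either side are
    excluded and logged rather than raised.
    """
    notes = decisions if decisions is not None else []
    if group_pairs is None:
        order = mb.group_order
        group_pairs = list(itertools.combinations(order, 2))
    prod = _set_group_means(ab.group_means(), producer_set.taxa)
    conc = mb.group_means()[producer_set.metabolite]
    records = []
    for gi, gj in group_pairs:
        pi, pj = float(prod[gi]), float(prod[gj])
        ci, cj = float(conc[gi]), float(conc[gj])
        if min(pi, pj, ci, cj) <= 0:
            notes.append(f"{producer_set.metabolite} ({gi}->{gj}): zero group "
                         "mean, pair excluded")
            log.warning("zero group mean for %s (%s->%s); pair excluded",
                        producer_set.metabolite, gi, gj)
            continue
        records.append(FoldChangeRecord(metabolite=producer_set.metabolite,
                                        group_i=gi, group_j=gj,
                                        f=pj / pi, g=cj / ci))
    return records


def match_rate(records: list[FoldChangeRecord]) -> float:
    """Fraction of records with concordant direction, ties (f=1 or g=1) excluded."""
    usable = [r for r in records if r.f != 1 and r.g != 1]
    if not usable:
        raise NoRecordsError("no records with f != 1 and g != 1")
    return sum(r.match for r in usable) / len(usable)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_pvalue(ab: AbundanceTable, mb: MetaboliteTable,
                       producer_sets: dict[str, ProducerSet],
                       qualifying_records: list[FoldChangeRecord],
                       n_perm: int = 10000, seed: int | None = None,
                       pool_mode: str = "per_source", strict: bool = False,
                       all_records: list[FoldChangeRecord] | None = None
                       ) -> ConcordanceResult:
    """Permutation P value for the producer–metabolite concordance.

    Producers are re-assigned uniformly at random without replacement, the
    total number of assigned producers matching the observed total. With
    ``pool_mode="per_source"`` (default) each metabolite's count is drawn
    from its own candidate pool, which also fixes the total; with
    ``"global"`` a single draw from the pooled candidates is randomly
    partitioned into the observed per-metabolite counts. A draw succeeds
    when f' >= f for every up-qualifying pair and f' <= f for every
    down-qualifying pair; P = (successes + 1)/(n_perm + 1).
    """
    if not qualifying_records:
        raise NoQualifyingPairsError("no qualifying (f, g) pairs")
    bad = [r for r in qualifying_records
           if not (r.qualifies_up or r.qualifies_down)]
    if bad:
        raise ValueError(f"non-qualifying records passed: {bad}")
    if seed is None and strict:
        raise SeedRequiredError("a seed is required in strict mode")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if pool_mode not in ("per_source", "global"):
        raise ValueError("pool_mode must be 'per_source' or 'global'")

    rng = np.random.default_rng(seed)
    means = ab.group_means()
    arr = means.to_numpy()
    col_of = {t: i for i, t in enumerate(means.columns)}
    row_of = {g: i for i, g in enumerate(means.index)}

    metabolites = sorted({r.metabolite for r in qualifying_records})
    pools, counts, tests = [], [], []
    for m in metabolites:
        pset = producer_sets[m]
        pool_idx = np.array(sorted(col_of[t] for t in pset.candidate_pool
                                   if t in col_of))
        pools.append(pool_idx)
        counts.append(len(pset.taxa))
        tests.append([(row_of[r.group_i], row_of[r.group_j], r.f, r.qualifies_up)
                      for r in qualifying_records if r.metabolite == m])

    successes = 0
    for _ in range(n_perm):
        if pool_mode == "per_source":
            draws = [rng.choice(pool, size=c, replace=False)
                     for pool, c in zip(pools, counts)]
        else:
            global_pool = np.unique(np.concatenate(pools))
            total = sum(counts)
            picked = rng.choice(global_pool, size=min(total, len(global_pool)),
                                replace=False)
            rng.shuffle(picked)
            draws, start = [], 0
            for c in counts:
                draws.append(picked[start:start + c])
                start += c
        ok = True
        for sel, recs in zip(draws, tests):
            sums = arr[:, sel].sum(axis=1)
            for gi, gj, f_obs, up in recs:
                if sums[gi] <= 0:
                    ok = False
                    break
                f_rand = sums[gj] / sums[gi]
                if (up and f_rand < f_obs) or (not up and f_rand > f_obs):
                    ok = False
                    break
            if not ok:
                break
        successes += ok

    records = all_records if all_records is not None else qualifying_records
    try:
        rate = match_rate(records)
    except NoRecordsError:
        rate = float("nan")
    return ConcordanceResult(
        records=list(records), qualifying_records=list(qualifying_records),
        match_rate=rate, p_value=(successes + 1) / (n_perm + 1),
        raw_success_rate=successes / n_perm, n_perm=n_perm, seed=seed,
        n_qualifying_pairs=len(qualifying_records), pool_mode=pool_mode)


def run_validation(net: Network, ab: AbundanceTable, mb: MetaboliteTable,
                   rank: str = "species", min_fold: float = 1.5,
                   n_perm: int = 10000, seed: int | None = None,
                   group_pairs: list[tuple[str, str]] | None = None,
                   pool_mode: str = "per_source") -> ConcordanceResult:
    """End-to-end pipeline: candidates -> fold changes -> match rate -> P.

    ``net`` should already be degradation-propagated so indirect exporters
    count as producers.
    """
    notes: list[str] = []
    candidates = select_candidates(net, ab, mb, rank=rank, min_fold=min_fold,
                                   decisions=notes)
    records: list[FoldChangeRecord] = []
    psets: dict[str, ProducerSet] = {}
    for metabolite, pset in candidates:
        psets[metabolite] = pset
        records.extend(fold_changes(ab, mb, pset, group_pairs, decisions=notes))
    qualifying = [r for r in records if r.qualifies_up or r.qualifies_down]
    if not qualifying:
        raise NoQualifyingPairsError(
            "no qualifying (f, g) pairs after candidate selection")
    result = permutation_pvalue(ab, mb, psets, qualifying, n_perm=n_perm,
                                seed=seed, pool_mode=pool_mode,
                                all_records=records)
    result.log = notes
    return result
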