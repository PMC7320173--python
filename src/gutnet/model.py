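"""Data model for bipartite organism-compound metabolic interaction networks.

The network couples organisms (microbial species, strains, genera, and a few
host cell types) to chemical compounds (small-molecule metabolites and
macromolecules) through signed, literature-referenced metabolic associations:

* ``import`` / ``export`` — transport of a small molecule into / out of the
  organism;
* ``degradation`` — breakdown of a macromolecule (starch, cellulose, mucin,
  ...) into small-molecule products, described by :class:`DegradationRule`.

A *negative* association records curated evidence that an organism can NOT
transport or degrade a compound; these are kept alongside the positive
events because they are valuable for pruning false-positive transport
reactions from automatically generated metabolic models.

All construction operations (:func:`consolidate_strains`,
:func:`propagate_degradation`, :func:`merge_networks`) are pure: the input
network is never mutated, a new :class:`Network` is returned.
"""

from __future__ import annotations

import copy
import itertools
import re
from dataclasses import dataclass, field, replace

from .errors import ConflictError, MissingRuleError

ACTIVITIES = ("import", "export", "degradation")
SIGNS = ("positive", "negative")
RANKS = ("species", "genus", "strain", "cell_type")
KINDS = ("microbe", "host_cell")
PROVENANCES = ("direct", "indirect_degradation")

#: id grammar of the published resource ("NJC19_" + five digits) and of the
#: reserved namespace used for generated records.
ASSOC_ID_RE = re.compile(r"^[A-Za-z0-9]+_\d{5}$")
GENERATED_PREFIX = "GEN_"


@dataclass
class Organism:
    """One organism node: a microbe (species/strain/genus) or a host cell type."""

    organism_id: str
    name: str
    rank: str = "species"
    kind: str = "microbe"
    ncbi_taxid: int | None = None
    lineage: dict[str, str] = field(default_factory=dict)
    sample_sources: list[str] = field(default_factory=list)

    @property
    def genus(self) -> str | None:
        """Genus from the lineage, falling back to the first name token."""
        if "genus" in self.lineage:
            return self.lineage["genus"]
        tok = self.name.split()
        return tok[0] if tok else None


@dataclass
class Compound:
    """One compound node: a small-molecule metabolite or a macromolecule."""

    compound_id: str
    name: str
    klass: str = "small_molecule"
    kegg_cid: str | None = None


@dataclass
class Association:
    """A signed (organism, compound, activity) metabolic association.

    ``provenance`` distinguishes directly curated transport events from
    export links inferred by degradation-product propagation.
    """

    assoc_id: str
    organism_id: str
    compound_id: str
    activity: str
    sign: str = "positive"
    refs: tuple[str, ...] = ()
    provenance: str = "direct"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.organism_id, self.compound_id, self.activity)


@dataclass
class DegradationRule:
    """Macromolecule -> small-molecule degradation products."""

    macromolecule_id: str
    product_ids: tuple[str, ...]


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_network`."""

    invariant: str
    record: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.violations)


@dataclass
class Network:
    """Container for organisms, compounds, associations, rules, references.

    ``organisms`` and ``compounds`` are keyed by their opaque ids;
    ``references`` maps reference keys (e.g. ``"17"``) to citation text.
    """

    organisms: dict[str, Organism] = field(default_factory=dict)
    compounds: dict[str, Compound] = field(default_factory=dict)
    associations: list[Association] = field(default_factory=list)
    degradation_rules: list[DegradationRule] = field(default_factory=list)
    references: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- lookups -------------------------------------------------------------

    def organism_by_name(self, name: str) -> Organism | None:
        for org in self.organisms.values():
            if org.name == name:
                return org
        return None

    def compound_by_name(self, name: str) -> Compound | None:
        for cpd in self.compounds.values():
            if cpd.name == name:
                return cpd
        return None

    def rule_for(self, macromolecule_id: str) -> DegradationRule | None:
        for rule in self.degradation_rules:
            if rule.macromolecule_id == macromolecule_id:
                return rule
        return None

    def positive_associations(self) -> list[Association]:
        return [a for a in self.associations if a.sign == "positive"]

    def copy(self) -> "Network":
        return copy.deepcopy(self)

    def next_generated_id(self) -> str:
        """Next free serial in the reserved ``GEN_#####`` namespace."""
        used = [
            int(a.assoc_id[len(GENERATED_PREFIX):])
            for a in self.associations
            if a.assoc_id.startswith(GENERATED_PREFIX)
            and a.assoc_id[len(GENERATED_PREFIX):].isdigit()
        ]
        return f"{GENERATED_PREFIX}{(max(used) + 1 if used else 1):05d}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(net: Network) -> ValidationReport:
    """Check every type invariant; violations are reported, never raised.

    The report is deterministic: rows are ordered by the offending record id
    (association id where applicable, otherwise the organism/compound/rule
    id), then by invariant name.
    """
    rows: list[Violation] = []

    for org in net.organisms.values():
        if org.kind == "microbe" and org.ncbi_taxid is None:
            rows.append(Violation("microbe_taxid", org.organism_id,
                                  f"microbe {org.name!r} lacks an NCBI taxid"))
        if org.kind == "host_cell" and org.rank != "cell_type":
            rows.append(Violation("host_cell_rank", org.organism_id,
                                  f"host cell {org.name!r} has rank {org.rank!r}"))
        if org.rank not in RANKS or org.kind not in KINDS:
            rows.append(Violation("enum", org.organism_id,
                                  f"bad rank/kind for {org.name!r}"))

    seen_nr: dict[tuple[str, str], str] = {}
    for org in sorted(net.organisms.values(), key=lambda o: o.organism_id):
        nr = (org.name, org.rank)
        if nr in seen_nr:
            rows.append(Violation("organism_name_rank_unique", org.organism_id,
                                  f"(name, rank) {nr} duplicates {seen_nr[nr]}"))
        else:
            seen_nr[nr] = org.organism_id

    seen_cname: dict[str, str] = {}
    for cpd in sorted(net.compounds.values(), key=lambda c: c.compound_id):
        if cpd.name in seen_cname:
            rows.append(Violation("compound_name_unique", cpd.compound_id,
                                  f"compound name {cpd.name!r} duplicates "
                                  f"{seen_cname[cpd.name]}"))
        else:
            seen_cname[cpd.name] = cpd.compound_id
        if cpd.klass not in ("small_molecule", "macromolecule"):
            rows.append(Violation("enum", cpd.compound_id,
                                  f"bad class {cpd.klass!r}"))

    by_key: dict[tuple[str, str, str], list[Association]] = {}
    for assoc in sorted(net.associations, key=lambda a: a.assoc_id):
        aid = assoc.assoc_id
        org = net.organisms.get(assoc.organism_id)
        cpd = net.compounds.get(assoc.compound_id)
        if org is None:
            rows.append(Violation("dangling_organism", aid,
                                  f"organism {assoc.organism_id!r} unresolved"))
        if cpd is None:
            rows.append(Violation("dangling_compound", aid,
                                  f"compound {assoc.compound_id!r} unresolved"))
        if assoc.activity not in ACTIVITIES or assoc.sign not in SIGNS \
                or assoc.provenance not in PROVENANCES:
            rows.append(Violation("enum", aid, "bad activity/sign/provenance"))
        if cpd is not None and assoc.activity in ACTIVITIES:
            if assoc.activity == "degradation" and cpd.klass != "macromolecule":
                rows.append(Violation("activity_class_mismatch", aid,
                                      f"degradation of small molecule {cpd.name!r}"))
            if assoc.activity in ("import", "export") and cpd.klass != "small_molecule":
                rows.append(Violation("activity_class_mismatch", aid,
                                      f"{assoc.activity} of macromolecule {cpd.name!r}"))
        by_key.setdefault(assoc.key, []).append(assoc)

    for key, group in sorted(by_key.items(), key=lambda kv: kv[1][0].assoc_id):
        if len(group) < 2:
            continue
        signs = {a.sign for a in group}
        ids = ", ".join(a.assoc_id for a in group)
        if len(signs) > 1:
            rows.append(Violation("sign_conflict", group[0].assoc_id,
                                  f"opposite signs for {key}: {ids}"))
        else:
            rows.append(Violation("association_key_unique", group[0].assoc_id,
                                  f"duplicate (organism, compound, activity) {key}: {ids}"))

    for rule in net.degradation_rules:
        rid = f"rule:{rule.macromolecule_id}"
        macro = net.compounds.get(rule.macromolecule_id)
        if macro is None:
            rows.append(Violation("dangling_compound", rid, "macromolecule unresolved"))
        elif macro.klass != "macromolecule":
            rows.append(Violation("rule_macromolecule_class", rid,
                                  f"{macro.name!r} is not a macromolecule"))
        if len(set(rule.product_ids)) != len(rule.product_ids):
            rows.append(Violation("rule_products_distinct", rid, "duplicate products"))
        if not rule.product_ids:
            rows.append(Violation("rule_products_nonempty", rid, "no products"))
        if rule.macromolecule_id in rule.product_ids:
            rows.append(Violation("rule_self_product", rid,
                                  "macromolecule among its own products"))
        for pid in rule.product_ids:
            pc = net.compounds.get(pid)
            if pc is None:
                rows.append(Violation("dangling_compound", rid,
                                      f"product {pid!r} unresolved"))
            elif pc.klass != "small_molecule":
                rows.append(Violation("rule_product_class", rid,
                                      f"product {pc.name!r} is not a small molecule"))

    for assoc in net.associations:
        for ref in assoc.refs:
            if ref not in net.references:
                rows.append(Violation("dangling_reference", assoc.assoc_id,
                                      f"reference key {ref!r} unresolved"))

    rows.sort(key=lambda v: (v.record, v.invariant, v.message))
    return ValidationReport(rows)


# ---------------------------------------------------------------------------
# construction operations
# ---------------------------------------------------------------------------

def _merge_refs(*ref_tuples: tuple[str, ...]) -> tuple[str, ...]:
    merged = sorted(set(itertools.chain.from_iterable(ref_tuples)))
    return tuple(merged)


def _dedupe_associations(assocs: list[Association]) -> list[Association]:
    """Union associations on (organism, compound, activity), merging refs.

    Raises ConflictError when a key carries both signs. Direct provenance
    wins over indirect when duplicates mix the two. Deterministic: keeps the
    smallest assoc_id of each group, iterating in sorted id order.
    """
    out: dict[tuple[str, str, str], Association] = {}
    for assoc in sorted(assocs, key=lambda a: a.assoc_id):
        prev = out.get(assoc.key)
        if prev is None:
            out[assoc.key] = assoc
            continue
        if prev.sign != assoc.sign:
            raise ConflictError(
                f"opposite signs for {assoc.key}: {prev.assoc_id} vs {assoc.assoc_id}")
        provenance = "direct" if "direct" in (prev.provenance, assoc.provenance) \
            else "indirect_degradation"
        out[assoc.key] = replace(prev, refs=_merge_refs(prev.refs, assoc.refs),
                                 provenance=provenance)
    return list(out.values())


def consolidate_strains(net: Network) -> Network:
    """Collapse strain-rank organisms into one species with the union of links.

    Every strain must carry its parent species name under ``lineage["species"]``.
    The species organism inherits the smallest strain taxid (deterministic) and
    the strain lineages minus the strain entry. Raises :class:`ConflictError`
    when two strains of one species contribute opposite signs for the same
    (compound, activity). Idempotent: a network without strains is returned
    unchanged (as a copy).
    """
    strains = [o for o in net.organisms.values() if o.rank == "strain"]
    if not strains:
        return net.copy()

    result = net.copy()
    id_map: dict[str, str] = {}
    by_species: dict[str, list[Organism]] = {}
    for strain in sorted(strains, key=lambda o: o.organism_id):
        sp_name = strain.lineage.get("species")
        if sp_name is None:
            raise ConflictError(
                f"strain {strain.name!r} lacks a species entry in its lineage")
        by_species.setdefault(sp_name, []).append(strain)

    for sp_name, members in sorted(by_species.items()):
        existing = next((o for o in result.organisms.values()
                         if o.name == sp_name and o.rank == "species"), None)
        if existing is None:
            first = min(members, key=lambda o: o.organism_id)
            taxids = sorted(o.ncbi_taxid for o in members if o.ncbi_taxid is not None)
            lineage = {k: v for k, v in first.lineage.items() if k != "strain"}
            lineage["species"] = sp_name
            sources = sorted({s for o in members for s in o.sample_sources})
            species = Organism(
                organism_id=sp_name, name=sp_name, rank="species", kind="microbe",
                ncbi_taxid=taxids[0] if taxids else None,
                lineage=lineage, sample_sources=sources)
            result.organisms[species.organism_id] = species
            target_id = species.organism_id
        else:
            target_id = existing.organism_id
        for strain in members:
            id_map[strain.organism_id] = target_id
            del result.organisms[strain.organism_id]

    remapped = [replace(a, organism_id=id_map.get(a.organism_id, a.organism_id))
                for a in result.associations]
    try:
        result.associations = _dedupe_associations(remapped)
    except ConflictError as err:
        raise ConflictError(f"strain consolidation: {err}") from None
    return result


def propagate_degradation(net: Network) -> Network:
    """Add indirect export links for every positive macromolecule degrader.

    Each species with a positive degradation association for macromolecule M
    becomes an exporter of every degradation product of M, with provenance
    ``indirect_degradation``. Existing direct exports are kept unchanged;
    negative degradation associations contribute nothing. Idempotent, never
    removes associations, never touches signs.
    """
    result = net.copy()
    existing = {a.key for a in result.associations}
    new: list[Association] = []
    serial = int(result.next_generated_id()[len(GENERATED_PREFIX):])
    for assoc in sorted(result.associations, key=lambda a: a.assoc_id):
        if assoc.activity != "degradation" or assoc.sign != "positive":
            continue
        rule = result.rule_for(assoc.compound_id)
        if rule is None:
            macro = result.compounds.get(assoc.compound_id)
            name = macro.name if macro else assoc.compound_id
            raise MissingRuleError(f"no degradation rule for macromolecule {name!r}")
        for pid in rule.product_ids:
            key = (assoc.organism_id, pid, "export")
            if key in existing:
                continue
            existing.add(key)
            new.append(Association(
                assoc_id=f"{GENERATED_PREFIX}{serial:05d}",
                organism_id=assoc.organism_id, compound_id=pid,
                activity="export", sign="positive", refs=assoc.refs,
                provenance="indirect_degradation"))
            serial += 1
    result.associations = result.associations + new
    return result


def merge_networks(a: Network, b: Network) -> Network:
    """Merge two networks through their shared organisms and compounds.

    Organisms are unified on NCBI taxid (falling back to (name, rank)),
    compounds on KEGG compound id (falling back to name); associations are
    unioned with de-duplication on (organism, compound, activity), and
    reference keys colliding with different citation text are renumbered
    deterministically (stable order by citation text). Merging with the
    empty network is the identity; the association sets of ``merge(a, b)``
    and ``merge(b, a)`` are equal.
    """
    result = a.copy()

    def org_key(o: Organism):
        return ("taxid", o.ncbi_taxid) if o.ncbi_taxid is not None \
            else ("name", o.name, o.rank)

    def cpd_key(c: Compound):
        return ("kegg", c.kegg_cid) if c.kegg_cid is not None else ("name", c.name)

    orgs_by_key = {org_key(o): oid for oid, o in result.organisms.items()}
    cpds_by_key = {cpd_key(c): cid for cid, c in result.compounds.items()}

    org_map: dict[str, str] = {}
    for oid, org in sorted(b.organisms.items()):
        match = orgs_by_key.get(org_key(org))
        if match is not None:
            org_map[oid] = match
            kept = result.organisms[match]
            if kept.ncbi_taxid is None:
                kept.ncbi_taxid = org.ncbi_taxid
            for k, v in org.lineage.items():
                kept.lineage.setdefault(k, v)
            kept.sample_sources = sorted(set(kept.sample_sources) | set(org.sample_sources))
        else:
            new_id = oid if oid not in result.organisms else f"{oid}*m"
            copied = replace(copy.deepcopy(org), organism_id=new_id)
            result.organisms[new_id] = copied
            orgs_by_key[org_key(copied)] = new_id
            org_map[oid] = new_id

    cpd_map: dict[str, str] = {}
    for cid, cpd in sorted(b.compounds.items()):
        match = cpds_by_key.get(cpd_key(cpd))
        if match is not None:
            cpd_map[cid] = match
            if result.compounds[match].kegg_cid is None:
                result.compounds[match].kegg_cid = cpd.kegg_cid
        else:
            new_id = cid if cid not in result.compounds else f"{cid}*m"
            copied = replace(cpd, compound_id=new_id)
            result.compounds[new_id] = copied
            cpds_by_key[cpd_key(copied)] = new_id
            cpd_map[cid] = new_id

    # references: reuse keys bound to identical citation text, renumber clashes
    text_to_key = {text: key for key, text in result.references.items()}
    ref_map: dict[str, str] = {}
    pending = sorted(b.references.items(), key=lambda kv: (kv[1], kv[0]))
    next_serial = 1
    for key, text in pending:
        if text in text_to_key:
            ref_map[key] = text_to_key[text]
        elif key not in result.references:
            result.references[key] = text
            text_to_key[text] = key
            ref_map[key] = key
        else:
            while str(next_serial) in result.references:
                next_serial += 1
            new_key = str(next_serial)
            result.references[new_key] = text
            text_to_key[text] = new_key
            ref_map[key] = new_key

    incoming = [replace(assoc,
                        organism_id=org_map[assoc.organism_id],
                        compound_id=cpd_map[assoc.compound_id],
                        refs=tuple(ref_map.get(r, r) for r in assoc.refs))
                for assoc in b.associations]
    try:
        result.associations = _dedupe_associations(result.associations + incoming)
    except ConflictError as err:
        raise ConflictError(f"network merge: {err}") from None

    rules: dict[str, set[str]] = {r.macromolecule_id: set(r.product_ids)
                                  for r in result.degradation_rules}
    for rule in b.degradation_rules:
        mid = cpd_map[rule.macromolecule_id]
        products = {cpd_map[p] for p in rule.product_ids}
        rules.setdefault(mid, set()).update(products)
    result.degradation_rules = [DegradationRule(mid, tuple(sorted(ps)))
                                for mid, ps in sorted(rules.items())]
    return result
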