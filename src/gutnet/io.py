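"""Readers and writers for the network JSON dialect and tabular inputs.

The JSON dialect mirrors the deposited NJC19 resource: four files, where the
network file is an array of association objects, each carrying the keys
``"Species"``, ``"Small-molecule metabolite or macromolecule"``,
``"Metabolic activity"`` and ``"Ref. #"`` (spelled byte-for-byte, trailing
``#`` included), plus an ``"ID"`` such as ``NJC19_00042``. Side files
annotate organisms with NCBI taxonomy ids and compounds with KEGG compound
ids, and resolve reference keys to citations.

Activity tokens are canonicalised to ``import``, ``export`` and
``degradation``; a negative association prepends ``not-`` (e.g.
``not-import``).  Because the controlled vocabulary of deposited files may
differ, readers accept a *dialect map* of alias -> canonical token.

Abundance tables are TSV with one row per sample (first column = sample id,
a ``group`` column, optional ``study`` column, remaining columns taxa);
metabolite tables are TSV with one row per replicate plus an optional
``host_or_diet_derived`` pseudo-row of 0/1 flags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (CrossRefError, NegativeValueError, ParseError, SchemaError)
from .model import (Association, Compound, DegradationRule, Network, Organism)

log = logging.getLogger(__name__)

K_ID = "ID"
K_SPECIES = "Species"
K_COMPOUND = "Small-molecule metabolite or macromolecule"
K_ACTIVITY = "Metabolic activity"
K_REF = "Ref. #"
K_PROVENANCE = "Provenance"
REQUIRED_KEYS = (K_SPECIES, K_COMPOUND, K_ACTIVITY, K_REF)

NEGATIVE_PREFIX = "not-"
REF_DELIM = "; "


def _parse_activity(token: str, dialect: dict[str, str] | None = None
                    ) -> tuple[str, str]:
    """Canonical (activity, sign) from an activity token, via the dialect map."""
    raw = token.strip()
    if dialect and raw in dialect:
        raw = dialect[raw]
    sign = "positive"
    if raw.startswith(NEGATIVE_PREFIX):
        sign = "negative"
        raw = raw[len(NEGATIVE_PREFIX):]
    if raw not in ("import", "export", "degradation"):
        raise SchemaError(f"unrecognised metabolic activity token {token!r}")
    return raw, sign


def _activity_token(activity: str, sign: str) -> str:
    return activity if sign == "positive" else NEGATIVE_PREFIX + activity


def _ref_sort_key(key: str):
    return (0, int(key)) if key.isdigit() else (1, key)


# ---------------------------------------------------------------------------
# network JSON dialect
# ---------------------------------------------------------------------------

def read_network_json(network_path, organism_path, compound_path,
                      reference_path, dialect: dict[str, str] | None = None
                      ) -> Network:
    """Parse the four-file JSON dialect into a :class:`Network`.

    Raises :class:`SchemaError` naming the first object missing a required
    key, and :class:`CrossRefError` when a network object names an organism
    or compound absent from the side files.
    """
    organisms: dict[str, Organism] = {}
    for obj in json.loads(Path(organism_path).read_text(encoding="utf-8")):
        name = obj[K_SPECIES]
        taxid = obj.get("NCBI taxonomy ID")
        organisms[name] = Organism(
            organism_id=name, name=name,
            rank=obj.get("Rank", "cell_type" if taxid is None else "species"),
            kind=obj.get("Kind", "host_cell" if taxid is None else "microbe"),
            ncbi_taxid=int(taxid) if taxid is not None else None,
            lineage=dict(obj.get("Lineage", {})),
            sample_sources=list(obj.get("Sample sources", [])))

    compounds: dict[str, Compound] = {}
    rules: list[DegradationRule] = []
    for obj in json.loads(Path(compound_path).read_text(encoding="utf-8")):
        name = obj[K_COMPOUND]
        klass = obj.get("Class",
                        "macromolecule" if obj.get("Degradation products")
                        else "small_molecule")
        compounds[name] = Compound(compound_id=name, name=name, klass=klass,
                                   kegg_cid=obj.get("KEGG compound ID"))
        products = obj.get("Degradation products")
        if products:
            rules.append(DegradationRule(name, tuple(products)))

    ref_raw = json.loads(Path(reference_path).read_text(encoding="utf-8"))
    if isinstance(ref_raw, dict):
        references = {str(k): str(v) for k, v in ref_raw.items()}
    else:
        references = {str(obj[K_REF]): str(obj.get("Citation", ""))
                      for obj in ref_raw}

    associations: list[Association] = []
    objs = json.loads(Path(network_path).read_text(encoding="utf-8"))
    for i, obj in enumerate(objs):
        oid = obj.get(K_ID, f"object #{i}")
        missing = [k for k in REQUIRED_KEYS if k not in obj]
        if missing:
            raise SchemaError(f"{oid}: missing key(s) {missing}")
        if obj[K_SPECIES] not in organisms:
            raise CrossRefError(f"{oid}: organism {obj[K_SPECIES]!r} "
                                "absent from the organism file")
        if obj[K_COMPOUND] not in compounds:
            raise CrossRefError(f"{oid}: compound {obj[K_COMPOUND]!r} "
                                "absent from the compound file")
        activity, sign = _parse_activity(obj[K_ACTIVITY], dialect)
        refs = tuple(r.strip() for r in str(obj[K_REF]).split(";") if r.strip())
        associations.append(Association(
            assoc_id=obj.get(K_ID, f"GEN_{i + 1:05d}"),
            organism_id=obj[K_SPECIES], compound_id=obj[K_COMPOUND],
            activity=activity, sign=sign, refs=refs,
            provenance=obj.get(K_PROVENANCE, "direct")))

    net = Network(organisms=organisms, compounds=compounds,
                  associations=associations, degradation_rules=rules,
                  references=references)
    log.info("read %d associations, %d organisms, %d compounds",
             len(associations), len(organisms), len(compounds))
    return net


def write_network_json(net: Network, out_dir) -> tuple[Path, Path, Path, Path]:
    """Write the four dialect files; output is byte-reproducible.

    Objects are sorted by id/name and dumped with sorted keys, so writing
    the same network twice yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(path: Path, payload) -> Path:
        path.write_text(json.dumps(payload, indent=1, ensure_ascii=False,
                                   sort_keys=True) + "\n", encoding="utf-8")
        return path

    net_objs = []
    for assoc in sorted(net.associations, key=lambda a: a.assoc_id):
        org = net.organisms[assoc.organism_id]
        cpd = net.compounds[assoc.compound_id]
        obj = {K_ID: assoc.assoc_id,
               K_SPECIES: org.name,
               K_COMPOUND: cpd.name,
               K_ACTIVITY: _activity_token(assoc.activity, assoc.sign),
               K_REF: REF_DELIM.join(assoc.refs)}
        if assoc.provenance != "direct":
            obj[K_PROVENANCE] = assoc.provenance
        net_objs.append(obj)

    org_objs = []
    for org in sorted(net.organisms.values(), key=lambda o: o.name):
        obj = {K_SPECIES: org.name, "Rank": org.rank, "Kind": org.kind,
               "NCBI taxonomy ID": org.ncbi_taxid}
        if org.lineage:
            obj["Lineage"] = dict(sorted(org.lineage.items()))
        if org.sample_sources:
            obj["Sample sources"] = sorted(org.sample_sources)
        org_objs.append(obj)

    rule_by_macro = {r.macromolecule_id: r for r in net.degradation_rules}
    cpd_objs = []
    for cpd in sorted(net.compounds.values(), key=lambda c: c.name):
        obj = {K_COMPOUND: cpd.name, "Class": cpd.klass,
               "KEGG compound ID": cpd.kegg_cid}
        rule = rule_by_macro.get(cpd.compound_id)
        if rule is not None:
            obj["Degradation products"] = [net.compounds[p].name
                                           for p in rule.product_ids]
        cpd_objs.append(obj)

    ref_objs = [{K_REF: k, "Citation": net.references[k]}
                for k in sorted(net.references, key=_ref_sort_key)]

    return (dump(out / "network.json", net_objs),
            dump(out / "organism.json", org_objs),
            dump(out / "compound.json", cpd_objs),
            dump(out / "reference.json", ref_objs))


# ---------------------------------------------------------------------------
# association table (supplementary-table style)
# ---------------------------------------------------------------------------

def network_to_table(net: Network) -> pd.DataFrame:
    """Project the association set onto the canonical tabular form.

    One row per association; the four canonical columns plus the id. The
    negative marker rides on the activity token (``not-import``); multiple
    references are ``"; "``-delimited.
    """
    rows = []
    for assoc in sorted(net.associations, key=lambda a: a.assoc_id):
        rows.append({K_ID: assoc.assoc_id,
                     K_SPECIES: net.organisms[assoc.organism_id].name,
                     K_COMPOUND: net.compounds[assoc.compound_id].name,
                     K_ACTIVITY: _activity_token(assoc.activity, assoc.sign),
                     K_REF: REF_DELIM.join(assoc.refs)})
    return pd.DataFrame(rows, columns=[K_ID, *REQUIRED_KEYS])


def table_to_network(table: pd.DataFrame, side: Network,
                     dialect: dict[str, str] | None = None) -> Network:
    """Inverse of :func:`network_to_table`, given a network providing the
    organism/compound/reference side information."""
    result = side.copy()
    associations = []
    for i, row in table.iterrows():
        org = result.organism_by_name(str(row[K_SPECIES]))
        cpd = result.compound_by_name(str(row[K_COMPOUND]))
        if org is None:
            raise CrossRefError(f"row {i}: unknown organism {row[K_SPECIES]!r}")
        if cpd is None:
            raise CrossRefError(f"row {i}: unknown compound {row[K_COMPOUND]!r}")
        activity, sign = _parse_activity(str(row[K_ACTIVITY]), dialect)
        refs = tuple(r.strip() for r in str(row.get(K_REF, "")).split(";")
                     if r.strip())
        associations.append(Association(
            assoc_id=str(row[K_ID]) if K_ID in table.columns else f"GEN_{i + 1:05d}",
            organism_id=org.organism_id, compound_id=cpd.compound_id,
            activity=activity, sign=sign, refs=refs))
    result.associations = associations
    return result


# ---------------------------------------------------------------------------
# abundance and metabolite tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Samples x taxa abundances with per-sample group (and study) labels."""

    data: pd.DataFrame                     # samples x taxa
    groups: pd.Series                      # sample -> group label
    rank: str = "species"
    mode: str = "relative"                 # or "absolute"
    studies: pd.Series | None = None       # sample -> study label

    def __post_init__(self):
        if (self.data.to_numpy() < 0).any():
            raise NegativeValueError("negative abundance value")
        if self.mode == "relative":
            sums = self.data.sum(axis=1)
            if (sums > 1 + 1e-6).any():
                bad = sums[sums > 1 + 1e-6].index[0]
                raise ParseError(
                    f"relative abundances of sample {bad!r} sum to {sums[bad]:.4g} > 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def group_order(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def group_means(self) -> pd.DataFrame:
        """Replicate-mean abundance per (group, taxon), groups in declared order."""
        return self.data.groupby(self.groups, sort=False).mean().reindex(self.group_order)


@dataclass
class MetaboliteTable:
    """Replicate-resolved metabolite concentrations per experimental group."""

    data: pd.DataFrame                     # replicates x metabolites
    groups: pd.Series                      # replicate -> group label
    host_or_diet_derived: pd.Series = None  # bool per metabolite
    units: str = ""

    def __post_init__(self):
        if (self.data.to_numpy() < 0).any():
            raise NegativeValueError("negative concentration value")
        if self.host_or_diet_derived is None:
            self.host_or_diet_derived = pd.Series(False, index=self.data.columns)
        missing = [m for m in self.data.columns
                   if m not in self.host_or_diet_derived.index]
        if missing:
            raise ParseError(f"host/diet flags missing for metabolites {missing}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def group_order(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def group_means(self) -> pd.DataFrame:
        return self.data.groupby(self.groups, sort=False).mean().reindex(self.group_order)


FLAG_ROW = "host_or_diet_derived"


def read_abundance_table(path, rank: str = "species", mode: str = "relative",
                         group_col: str = "group", study_col: str = "study"
                         ) -> AbundanceTable:
    """Read a samples x taxa TSV (first column sample id, ``group`` column).

    Percent-convention inputs (row sums near 100) are detected and rescaled
    to fractions with a logged warning.
    """
    df = _read_tsv(path)
    if group_col not in df.columns:
        raise ParseError(f"{path}: missing required column {group_col!r}")
    groups = df[group_col].astype(str)
    studies = df[study_col].astype(str) if study_col in df.columns else None
    taxa_cols = [c for c in df.columns if c not in (group_col, study_col)]
    values = df[taxa_cols].apply(pd.to_numeric, errors="raise")
    if (values.to_numpy() < 0).any():
        raise NegativeValueError(f"{path}: negative abundance value")
    if mode == "relative":
        sums = values.sum(axis=1)
        if len(sums) and float(np.median(sums)) > 1.5:
            log.warning("%s: row sums ~%.1f look like percentages; rescaling "
                        "to fractions", path, float(np.median(sums)))
            values = values / 100.0
    return AbundanceTable(data=values, groups=groups, rank=rank, mode=mode,
                          studies=studies)


def read_metabolite_table(path, group_col: str = "group", units: str = ""
                          ) -> MetaboliteTable:
    """Read a replicates x metabolites TSV.

    A pseudo-row whose group label is ``host_or_diet_derived`` carries the
    per-metabolite 0/1 host/diet flags and is not treated as a replicate.
    """
    df = _read_tsv(path)
    if group_col not in df.columns:
        raise ParseError(f"{path}: missing required column {group_col!r}")
    flags_mask = df[group_col].astype(str) == FLAG_ROW
    metab_cols = [c for c in df.columns if c != group_col]
    flags = pd.Series(False, index=metab_cols)
    if flags_mask.any():
        flag_row = df.loc[flags_mask, metab_cols].iloc[0]
        flags = flag_row.astype(float).astype(bool)
        df = df.loc[~flags_mask]
    values = df[metab_cols].apply(pd.to_numeric, errors="raise")
    if (values.to_numpy() < 0).any():
        raise NegativeValueError(f"{path}: negative concentration value")
    return MetaboliteTable(data=values, groups=df[group_col].astype(str),
                           host_or_diet_derived=flags, units=units)


def write_abundance_table(ab: AbundanceTable, path) -> Path:
    df = ab.data.copy()
    df.insert(0, "group", ab.groups)
    if ab.studies is not None:
        df.insert(1, "study", ab.studies)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    return Path(path)


def write_metabolite_table(mb: MetaboliteTable, path) -> Path:
    df = mb.data.copy()
    df.insert(0, "group", mb.groups)
    flag_row = pd.DataFrame(
        [[FLAG_ROW, *mb.host_or_diet_derived.reindex(mb.data.columns).astype(int)]],
        columns=df.columns, index=["flags"])
    out = pd.concat([flag_row, df])
    out.index.name = "replicate"
    out.to_csv(path, sep="\t")
    return Path(path)


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as err:
        raise ParseError(f"{path}: {err}") from None
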