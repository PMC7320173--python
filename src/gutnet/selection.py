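"""Prevalence-based species selection from metagenome abundance tables.

The network-construction pipeline starts from taxonomic profiles of many
fecal/cecal metagenome samples and keeps, within each study, the species
detected (relative abundance >= 0.001%) in at least 90% of that study's
samples. Both thresholds are inclusive. The genus-coverage summary then
reports which fraction of total microbial abundance the genera of the
selected species account for, per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, RankError
from .io import AbundanceTable


@dataclass
class SelectionParams:
    """Thresholds of the prevalence filter.

    prevalence_min
        Minimum fraction of a study's samples in which a species must be
        detected (default 0.90, i.e. ">= 90% of the samples").
    abundance_min
        Detection threshold on relative abundance (default 1e-5, i.e.
        0.001%).
    per_study
        Apply the filter within each study separately; a species qualifies
        if it passes in any study (each study contributes its own list).
    """

    prevalence_min: float = 0.90
    abundance_min: float = 1e-5
    per_study: bool = True

    def __post_init__(self):
        if not (0 < self.prevalence_min <= 1):
            raise ValueError("prevalence_min must be in (0, 1]")
        if not (0 < self.abundance_min < 1):
            raise ValueError("abundance_min must be in (0, 1)")


def prevalence(ab: AbundanceTable, abundance_min: float) -> pd.Series:
    """Fraction of samples where each taxon is at or above ``abundance_min``."""
    return (ab.data >= abundance_min).mean(axis=0)


def select_prevalent_species(ab: AbundanceTable,
                             params: SelectionParams | None = None
                             ) -> list[str]:
    """Species passing the prevalence filter, most prevalent first.

    With ``per_study`` and a study column present, the filter runs within
    each study and the union of the per-study lists is returned. Output is
    sorted by descending pooled prevalence, ties broken by name.
    """
    params = params or SelectionParams()
    if ab.rank != "species":
        raise RankError(f"species selection needs a species-rank table, "
                        f"got {ab.rank!r}")
    if ab.mode != "relative":
        raise RankError("species selection needs relative abundances")

    detected = ab.data >= params.abundance_min
    if params.per_study and ab.studies is not None:
        passed: set[str] = set()
        for _, mask in detected.groupby(ab.studies, sort=False):
            frac = mask.mean(axis=0)
            passed |= set(frac.index[frac >= params.prevalence_min])
    else:
        frac = detected.mean(axis=0)
        passed = set(frac.index[frac >= params.prevalence_min])

    pooled = detected.mean(axis=0)
    return sorted(passed, key=lambda t: (-pooled[t], t))


def genus_coverage(ab: AbundanceTable, selected: list[str],
                   genus_map: dict[str, str] | None = None
                   ) -> tuple[float, float, pd.Series]:
    """Abundance fraction covered by the genera of the selected species.

    Per sample: the summed relative abundance of all species whose genus
    appears among the genera of ``selected``, divided by the sample's total
    microbial abundance. Returns (mean, sample s.d. with the n-1
    denominator, per-sample fractions). The genus of a taxon is taken from
    ``genus_map`` when given, otherwise from the first whitespace token of
    its name (binomial convention).
    """
    if not selected:
        raise EmptySelectionError("no species selected")

    def genus_of(name: str) -> str:
        if genus_map and name in genus_map:
            return genus_map[name]
        return name.split()[0]

    selected_genera = {genus_of(t) for t in selected}
    covered_cols = [t for t in ab.taxa if genus_of(t) in selected_genera]
    totals = ab.data.sum(axis=1)
    covered = ab.data[covered_cols].sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = (covered / totals).fillna(0.0)
    mean = float(frac.mean())
    sd = float(frac.std(ddof=1)) if len(frac) > 1 else 0.0
    return mean, sd, frac
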