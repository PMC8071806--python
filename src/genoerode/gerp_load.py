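"""GERP-weighted relative mutational load and deleterious-allele sharing.

Relative load for an individual is the conservation-score-weighted mean of
its derived alleles at evolutionarily constrained sites: the sum over
included sites of derived dosage times GERP score, divided by the sum of
derived dosages, where a site is included when its score exceeds a
threshold (default 4, the conventional "highly constrained" cut-off; 1 for
a non-neutral definition).  This is a per-allele average deleteriousness,
not an absolute mutation count, which makes it comparable across
individuals with different callable fractions.

Allele sharing between populations is estimated with a fixed-depth
subsample — six alleles per population per site, removing sample-size bias —
classifying each deleterious derived allele as unique to one population,
shared by a pair, or shared by all.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import VariantDataset

__all__ = ["LoadResult", "SharingResult", "relative_load", "allele_sharing"]


@dataclass(frozen=True)
class LoadResult:
    sample_id: str
    relative_load: float  # NaN when undefined
    n_derived_included: int
    score_threshold: float
    defined: bool


@dataclass(frozen=True)
class SharingResult:
    """Category percentages over sites where >= 1 subsample carries the allele.

    Keys of ``percent``: ``unique:<pop>``, ``pair:<popA>+<popB>`` (sorted),
    ``all``.
    """

    percent: dict[str, float]
    n_sites_used: int
    n_alleles: int
    score_threshold: float
    seed: int


def relative_load(
    data: VariantDataset,
    sample_id: str,
    score_threshold: float = 4.0,
    *,
    all_derived_denominator: bool = False,
) -> LoadResult:
    """Score-weighted average deleteriousness of one sample's derived alleles.

    Sites enter the numerator only when their GERP score exceeds
    ``score_threshold``; sites with a missing genotype or unknown ancestral
    allele are excluded throughout.  With ``all_derived_denominator`` the
    denominator instead counts derived alleles at every scored site (a
    sensitivity variant).  A zero denominator yields a flagged undefined
    result rather than a division by zero.
    """
    j = data.sample_index(sample_id)
    dd = data.derived_dosage()[:, j]
    score = data.sites["gerp"].to_numpy()
    usable = ~np.isnan(dd) & ~np.isnan(score)
    included = usable & (score > score_threshold)
    numer = float(np.sum(dd[included] * score[included]))
    n_included = int(np.sum(dd[included]))
    denom = float(np.sum(dd[usable])) if all_derived_denominator else float(n_included)
    if denom <= 0:
        return LoadResult(sample_id, float("nan"), n_included, score_threshold, False)
    return LoadResult(sample_id, numer / denom, n_included, score_threshold, True)


def allele_sharing(
    data: VariantDataset,
    populations: Sequence[str],
    n_alleles: int = 6,
    score_threshold: float = 4.0,
    seed: int = 0,
    *,
    era: str | None = "modern",
) -> SharingResult:
    """Private/shared classification of deleterious derived alleles.

    At every site with GERP score above ``score_threshold`` where each
    population has at least ``n_alleles`` non-missing alleles, ``n_alleles``
    alleles are drawn without replacement per population; a population
    carries the derived allele iff at least one drawn allele is derived.
    Sites carried by no population are dropped.  Percentages are reported
    over the remaining sites and sum to 100.  ``era`` restricts the allele
    pools (``None`` uses all samples).
    """
    if len(populations) < 2:
        raise ValueError("allele sharing requires at least two populations")
    rng = np.random.default_rng(seed)
    score = data.sites["gerp"].to_numpy()
    site_ok = ~np.isnan(score) & (score > score_threshold)

    acs, ans = [], []
    for pop in populations:
        mask = data.population_mask(pop, era)
        if mask.sum() == 0:
            raise ValueError(f"no samples for population {pop!r}" + (f" in era {era!r}" if era else ""))
        ac, an = data.derived_allele_counts(mask)
        acs.append(ac)
        ans.append(an)
    ac = np.column_stack(acs)  # derived allele counts, sites x pops
    an = np.column_stack(ans)
    site_ok &= (an >= n_alleles).all(axis=1)
    idx = np.flatnonzero(site_ok)

    # hypergeometric draw: number of derived among n_alleles sampled without
    # replacement from the population's allele pool
    carries = np.zeros((idx.size, len(populations)), dtype=bool)
    for k in range(len(populations)):
        good = ac[idx, k].astype(np.int64)
        bad = (an[idx, k] - ac[idx, k]).astype(np.int64)
        drawn = rng.hypergeometric(good, bad, n_alleles)
        carries[:, k] = drawn >= 1

    any_carrier = carries.any(axis=1)
    carries = carries[any_carrier]
    n_used = int(carries.shape[0])

    counts: dict[str, int] = {f"unique:{p}": 0 for p in populations}
    for a, b in itertools.combinations(sorted(populations), 2):
        counts[f"pair:{a}+{b}"] = 0
    counts["all"] = 0
    pop_arr = np.array(populations)
    for row in carries:
        carriers = pop_arr[row]
        if carriers.size == 1:
            counts[f"unique:{carriers[0]}"] += 1
        elif carriers.size == len(populations):
            counts["all"] += 1
        else:
            a, b = sorted(carriers)
            counts[f"pair:{a}+{b}"] += 1
    percent = {
        k: (100.0 * v / n_used if n_used else float("nan")) for k, v in counts.items()
    }
    return SharingResult(percent, n_used, n_alleles, score_threshold, seed)


def load_table(
    data: VariantDataset, score_threshold: float = 4.0
) -> pd.DataFrame:
    """Per-sample relative-load table (sample, population, era, load, n alleles)."""
    rows = []
    for _, s in data.samples.iterrows():
        r = relative_load(data, s["id"], score_threshold)
        rows.append(
            (s["id"], s["population"], s["era"], r.relative_load, r.n_derived_included, r.defined)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "population", "era", "relative_load", "n_derived_included", "defined"],
    )
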