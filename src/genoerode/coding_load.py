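"""Coding-region burden: LoF / missense counts, fixed & private variants,
and translocation risk for assisted gene flow.

Effect categories (synonymous, missense, loss-of-function) are consumed as
annotations, never predicted here.  Per-individual burden counts variant
sites carried (derived dosage >= 1), split by zygosity; per-population
summaries partition loss-of-function sites into fixed (every non-missing
genotype homozygous derived) and private (derived frequency positive here,
zero in every other population).  Translocation risk counts the LoF variants
a candidate donor would introduce into a recipient population — those the
donor carries but that are absent from the recipient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import VariantDataset

__all__ = [
    "BurdenResult",
    "PopulationVariantSummary",
    "burden",
    "population_summary",
    "translocation_risk",
    "burden_table",
]

_CATEGORIES = ("lof", "missense", "synonymous")


@dataclass(frozen=True)
class BurdenResult:
    """Per-sample carried-site counts by effect category and zygosity."""

    sample_id: str
    n_lof_total: int
    n_lof_hom: int
    n_lof_het: int
    n_missense_total: int
    n_missense_hom: int
    n_missense_het: int
    n_synonymous_total: int
    n_synonymous_hom: int
    n_synonymous_het: int
    n_sites_skipped_missing: int


@dataclass
class PopulationVariantSummary:
    population: str
    n_lof_sites: int  # LoF sites segregating or fixed in the population
    n_genes_with_lof: int
    gene_lof_counts: pd.Series  # per-gene count of carried LoF sites
    fixed_sites: np.ndarray  # site indices, derived dosage 2 in all non-missing samples
    private_sites: np.ndarray  # AF > 0 here, AF = 0 in every other population
    private_and_fixed_sites: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _effect_sites(data: VariantDataset, effect: str) -> np.ndarray:
    idx = np.flatnonzero((data.sites["effect"] == effect).to_numpy())
    if idx.size == 0 and not (data.sites["effect"] != "none").any():
        raise ValueError("dataset carries no effect annotations")
    return idx


def burden(
    data: VariantDataset, sample_id: str, *, count_alleles: bool = False
) -> BurdenResult:
    """Count annotated variant sites carried by one sample.

    A site is carried when the derived dosage is >= 1; heterozygous and
    homozygous-derived states are tallied separately and missing genotypes
    (or unknown ancestral states) are skipped.  ``count_alleles`` switches
    the totals from carried sites to derived-allele counts (hom counts 2).
    """
    j = data.sample_index(sample_id)
    dd = data.derived_dosage()[:, j]
    effects = data.sites["effect"].to_numpy()
    if not (effects != "none").any():
        raise ValueError("dataset carries no effect annotations")
    counts = {}
    skipped = 0
    for cat in _CATEGORIES:
        at = effects == cat
        d = dd[at]
        skipped += int(np.isnan(d).sum())
        het = int((d == 1).sum())
        hom = int((d == 2).sum())
        total = het + 2 * hom if count_alleles else het + hom
        counts[cat] = (total, hom, het)
    return BurdenResult(
        sample_id=sample_id,
        n_lof_total=counts["lof"][0],
        n_lof_hom=counts["lof"][1],
        n_lof_het=counts["lof"][2],
        n_missense_total=counts["missense"][0],
        n_missense_hom=counts["missense"][1],
        n_missense_het=counts["missense"][2],
        n_synonymous_total=counts["synonymous"][0],
        n_synonymous_hom=counts["synonymous"][1],
        n_synonymous_het=counts["synonymous"][2],
        n_sites_skipped_missing=skipped,
    )


def population_summary(
    data: VariantDataset,
    population: str,
    *,
    era: str | None = None,
    min_call_rate: float = 0.0,
) -> PopulationVariantSummary:
    """LoF site partition for one population.

    Fixed requires every non-missing genotype homozygous derived (an
    optional call-rate floor guards against single-call "fixation").
    Private requires derived frequency > 0 here and 0 in every other
    population; populations with no calls at a site do not veto privacy.
    """
    mask = data.population_mask(population, era)
    if mask.sum() == 0:
        raise ValueError(f"empty population {population!r}")
    lof_idx = _effect_sites(data, "lof")
    dd = data.derived_dosage()[lof_idx]

    own = dd[:, mask]
    n_called = (~np.isnan(own)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        af = np.nansum(own, axis=1) / np.maximum(2 * n_called, 1)
    present = (af > 0) & (n_called > 0)

    call_rate = n_called / max(int(mask.sum()), 1)
    fixed = (
        present
        & (n_called > 0)
        & (call_rate >= min_call_rate)
        & np.all(np.isnan(own) | (own == 2), axis=1)
    )

    other_present = np.zeros(lof_idx.size, dtype=bool)
    for pop in data.populations():
        if pop == population:
            continue
        omask = data.population_mask(pop, era)
        if omask.sum() == 0:
            continue
        o = dd[:, omask]
        other_present |= np.nansum(o, axis=1) > 0
    private = present & ~other_present

    genes = data.sites["gene"].to_numpy()[lof_idx][present]
    gene_counts = pd.Series(genes[genes != ""]).value_counts().sort_index()
    return PopulationVariantSummary(
        population=population,
        n_lof_sites=int(present.sum()),
        n_genes_with_lof=int(gene_counts.size),
        gene_lof_counts=gene_counts,
        fixed_sites=lof_idx[fixed],
        private_sites=lof_idx[private],
        private_and_fixed_sites=lof_idx[fixed & private],
    )


def translocation_risk(
    data: VariantDataset,
    donor_id: str,
    recipient_population: str,
    *,
    recipient_era: str | None = None,
) -> tuple[int, np.ndarray]:
    """Count the donor's LoF variants absent from the recipient population.

    Returns the count and the site indices.  The donor must not belong to
    the recipient population.
    """
    j = data.sample_index(donor_id)
    if data.samples["population"].iloc[j] == recipient_population:
        raise ValueError(
            f"donor {donor_id!r} is a member of recipient population {recipient_population!r}"
        )
    rmask = data.population_mask(recipient_population, recipient_era)
    if rmask.sum() == 0:
        raise ValueError(f"empty recipient population {recipient_population!r}")
    lof_idx = _effect_sites(data, "lof")
    dd = data.derived_dosage()[lof_idx]
    donor_carries = dd[:, j] >= 1
    rec = dd[:, rmask]
    rec_called = (~np.isnan(rec)).sum(axis=1) > 0
    rec_absent = rec_called & (np.nansum(rec, axis=1) == 0)
    risky = donor_carries & rec_absent
    return int(risky.sum()), lof_idx[risky]


def burden_table(data: VariantDataset, *, count_alleles: bool = False) -> pd.DataFrame:
    """Per-sample burden table across all effect categories."""
    rows = []
    for _, s in data.samples.iterrows():
        b = burden(data, s["id"], count_alleles=count_alleles)
        rows.append(
            (
                s["id"], s["population"], s["era"],
                b.n_lof_total, b.n_lof_hom, b.n_lof_het,
                b.n_missense_total, b.n_missense_hom, b.n_missense_het,
                b.n_synonymous_total, b.n_synonymous_hom, b.n_synonymous_het,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "population", "era",
            "n_lof", "n_lof_hom", "n_lof_het",
            "n_missense", "n_missense_hom", "n_missense_het",
            "n_synonymous", "n_synonymous_hom", "n_synonymous_het",
        ],
    )
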