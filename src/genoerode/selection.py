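"""Per-gene population branch statistic (PBS) scan and missense summaries.

For three populations A, B, C the PBS of A at a locus is

    PBS_A = (T_AB + T_AC - T_BC) / 2,      T = -ln(1 - F_ST)

— the length of A's branch on the three-population tree, elevated when
allele frequencies at the locus moved specifically along A's lineage.
Per-gene F_ST uses the Hudson estimator with ratio-of-averages across the
gene's SNPs, the small-sample-robust convention for n of a few diploids per
population.  An F_ST of 1 makes T (and PBS) infinite; infinite PBS values
are replaced by the population's maximum finite PBS before outlier calling.
Outliers are genes with PBS above a hard threshold (default 3, roughly the
99.8th percentile under typical background drift); the percentile itself is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import VariantDataset

__all__ = [
    "hudson_fst_components",
    "pairwise_fst",
    "pbs",
    "pbs_scan",
    "cap_and_call",
    "OutlierCalls",
    "MissenseSummary",
    "missense_summary",
]


def hudson_fst_components(
    ac1: np.ndarray, an1: np.ndarray, ac2: np.ndarray, an2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson F_ST numerator and denominator.

    ``ac``/``an`` are alternate (or derived) allele counts and total called
    allele numbers per site.  num = (p1-p2)^2 - p1(1-p1)/(an1-1)
    - p2(1-p2)/(an2-1); den = p1(1-p2) + p2(1-p1).  Sites need an >= 2 in
    both populations; others return NaN components.
    """
    ac1, an1, ac2, an2 = (np.asarray(x, dtype=float) for x in (ac1, an1, ac2, an2))
    ok = (an1 >= 2) & (an2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, ac1 / np.maximum(an1, 1), np.nan)
        p2 = np.where(ok, ac2 / np.maximum(an2, 1), np.nan)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (an1 - 1) - p2 * (1 - p2) / (an2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _gene_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-averages gene-level F_ST, clamped to [0, 1]; NaN if no data."""
    ok = ~np.isnan(num) & ~np.isnan(den)
    if not ok.any():
        return float("nan")
    d = float(den[ok].sum())
    if d <= 0:
        # denominator zero: both populations monomorphic at every SNP
        return float("nan")
    return float(min(max(num[ok].sum() / d, 0.0), 1.0))


def pairwise_fst(
    data: VariantDataset,
    site_idx: np.ndarray,
    pop1: str,
    pop2: str,
    *,
    era: str | None = None,
) -> float:
    """Hudson F_ST between two populations over a set of sites (e.g. a gene)."""
    m1 = data.population_mask(pop1, era)
    m2 = data.population_mask(pop2, era)
    ac1, an1 = data.alt_allele_counts(m1)
    ac2, an2 = data.alt_allele_counts(m2)
    num, den = hudson_fst_components(
        ac1[site_idx], an1[site_idx], ac2[site_idx], an2[site_idx]
    )
    return _gene_fst(num, den)


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> tuple[float, float, float]:
    """Population branch statistics (PBS_A, PBS_B, PBS_C) from pairwise F_ST.

    T = -ln(1 - F_ST); F_ST = 1 propagates an infinite branch.  Inputs
    outside [0, 1] raise ``ValueError``; negative PBS is allowed.
    """
    for f in (fst_ab, fst_ac, fst_bc):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"F_ST {f} outside [0, 1]")
    with np.errstate(divide="ignore"):
        t_ab, t_ac, t_bc = (-np.log1p(-f) for f in (fst_ab, fst_ac, fst_bc))
    return (
        (t_ab + t_ac - t_bc) / 2.0,
        (t_ab + t_bc - t_ac) / 2.0,
        (t_ac + t_bc - t_ab) / 2.0,
    )


def pbs_scan(
    data: VariantDataset,
    genes: pd.DataFrame,
    populations: Sequence[str],
    *,
    era: str | None = None,
) -> pd.DataFrame:
    """Per-gene F_ST triple and PBS for three populations.

    ``genes`` has 1-based inclusive ``chrom, start, end, gene`` rows; a
    gene's SNP set is every biallelic SNP overlapping its interval (SNPs in
    overlapping genes count for each).  Genes without usable SNPs are
    flagged ``no_data`` and excluded from percentile computations.
    """
    if len(populations) != 3:
        raise ValueError("PBS requires exactly three populations")
    a, b, c = populations
    masks = {p: data.population_mask(p, era) for p in populations}
    counts = {p: data.alt_allele_counts(masks[p]) for p in populations}

    chroms = data.sites["chrom"].to_numpy()
    pos = data.sites["pos"].to_numpy()
    snp = ~data.sites["is_indel"].to_numpy()

    rows = []
    for r in genes.itertuples():
        in_gene = (chroms == r.chrom) & (pos >= r.start) & (pos <= r.end) & snp
        idx = np.flatnonzero(in_gene)
        pair_fst = {}
        for p1, p2, key in ((a, b, "ab"), (a, c, "ac"), (b, c, "bc")):
            num, den = hudson_fst_components(
                counts[p1][0][idx], counts[p1][1][idx],
                counts[p2][0][idx], counts[p2][1][idx],
            )
            pair_fst[key] = _gene_fst(num, den)
        no_data = any(np.isnan(v) for v in pair_fst.values()) or idx.size == 0
        if no_data:
            pbs_a = pbs_b = pbs_c = float("nan")
        else:
            pbs_a, pbs_b, pbs_c = pbs(pair_fst["ab"], pair_fst["ac"], pair_fst["bc"])
        rows.append(
            (
                r.gene, int(idx.size),
                pair_fst["ab"], pair_fst["ac"], pair_fst["bc"],
                pbs_a, pbs_b, pbs_c, no_data,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "n_snps", "fst_ab", "fst_ac", "fst_bc",
            f"pbs_{a}", f"pbs_{b}", f"pbs_{c}", "no_data",
        ],
    )


@dataclass
class OutlierCalls:
    """Per-population outlier calls after infinite-value capping."""

    capped: pd.DataFrame  # gene x population PBS with infinities replaced
    percentile_value: dict[str, float]  # the reported percentile per population
    outliers: dict[str, list[str]]  # genes with PBS > threshold
    unique_outliers: dict[str, list[str]]  # outlying in exactly one population
    all_fst_one: list[str]  # genes with F_ST = 1 in every pairwise comparison
    n_infinite_replaced: dict[str, int]
    threshold: float
    percentile: float


def cap_and_call(
    scan: pd.DataFrame,
    populations: Sequence[str],
    threshold: float = 3.0,
    percentile: float = 99.8,
) -> OutlierCalls:
    """Replace infinite PBS by the per-population finite maximum and call outliers.

    Capping never reorders finite values.  Outliers are genes with capped
    PBS strictly above ``threshold``; the requested percentile (linear
    interpolation) is reported for context.
    """
    usable = scan[~scan["no_data"]].copy()
    capped = usable[["gene"]].copy()
    pct_val: dict[str, float] = {}
    outliers: dict[str, list[str]] = {}
    n_inf: dict[str, int] = {}
    for pop in populations:
        col = usable[f"pbs_{pop}"].to_numpy(dtype=float)
        inf = np.isinf(col)
        finite = col[~inf & ~np.isnan(col)]
        if finite.size == 0:
            raise ValueError(f"all PBS values infinite for population {pop!r}")
        # +inf -> finite maximum (the reported rule); -inf -> finite minimum
        col = np.where(np.isposinf(col), finite.max(), col)
        col = np.where(np.isneginf(col), finite.min(), col)
        capped[f"pbs_{pop}"] = col
        n_inf[pop] = int(inf.sum())
        pct_val[pop] = float(np.percentile(col[~np.isnan(col)], percentile))
        outliers[pop] = list(usable["gene"].to_numpy()[col > threshold])
    unique = {
        pop: sorted(
            set(outliers[pop]).difference(
                *[set(outliers[q]) for q in populations if q != pop]
            )
        )
        for pop in populations
    }
    fst1 = usable[
        np.isclose(usable[["fst_ab", "fst_ac", "fst_bc"]], 1.0).all(axis=1)
    ]["gene"].tolist()
    return OutlierCalls(
        capped=capped,
        percentile_value=pct_val,
        outliers=outliers,
        unique_outliers=unique,
        all_fst_one=fst1,
        n_infinite_replaced=n_inf,
        threshold=threshold,
        percentile=percentile,
    )


@dataclass(frozen=True)
class MissenseSummary:
    population: str
    genes_with_missense: tuple[str, ...]
    genes_exclusive: tuple[str, ...]
    genes_with_fixed_missense: tuple[str, ...]


def missense_summary(
    data: VariantDataset,
    populations: Sequence[str],
    *,
    era: str | None = None,
    exclude_fixed_in_all: bool = True,
) -> dict[str, MissenseSummary]:
    """Genes with missense variants present / exclusive / fixed per population.

    A population "has" a missense variant when its derived frequency is
    positive; "fixed" means frequency 1 over non-missing calls.  Variants
    fixed in every population carry no comparative signal and are excluded
    by default.
    """
    mis = np.flatnonzero((data.sites["effect"] == "missense").to_numpy())
    genes = data.sites["gene"].to_numpy()[mis]
    af = {}
    for pop in populations:
        mask = data.population_mask(pop, era)
        af[pop] = data.derived_allele_freq(mask)[mis]
    if exclude_fixed_in_all and mis.size:
        fixed_everywhere = np.ones(mis.size, dtype=bool)
        for pop in populations:
            fixed_everywhere &= af[pop] == 1.0
        keep = ~fixed_everywhere
        mis, genes = mis[keep], genes[keep]
        af = {p: v[keep] for p, v in af.items()}

    out = {}
    for pop in populations:
        present = af[pop] > 0
        others = np.zeros(mis.size, dtype=bool)
        for q in populations:
            if q != pop:
                others |= af[q] > 0
        exclusive = present & ~others
        fixed = af[pop] == 1.0
        out[pop] = MissenseSummary(
            population=pop,
            genes_with_missense=tuple(sorted(set(genes[present]) - {""})),
            genes_exclusive=tuple(sorted(set(genes[exclusive]) - {""})),
            genes_with_fixed_missense=tuple(sorted(set(genes[present & fixed]) - {""})),
        )
    return out
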