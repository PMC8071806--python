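"""Synthetic multi-population variant datasets with known ground truth.

The generator emulates the data layout of a small-population resequencing
study: three diverged populations (two of them sampled in both a historical
and a modern era), a few tens of thousands of biallelic sites on a handful of
megabase-scale scaffolds, per-site conservation (GERP) scores, gene-localized
effect categories (synonymous / missense / loss-of-function) and per-sample
mean coverage.

Population structure follows the Balding-Nichols model: each population's
site frequency is a Beta draw around the ancestral frequency with variance
set by a per-population drift parameter, which doubles as the expected
pairwise F_ST scale.  Inbreeding is realized literally, as planted
identity-by-descent tracts: inside a tract both haplotypes are forced
identical, giving an exact per-sample truth F (tract length over genome
length) for recovery tests of the ROH detector.

All randomness flows from a single seeded generator, so a fixed config and
seed reproduce the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, VariantDataset, write_vcf

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "plant_roh",
    "default_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Defaults emulate a three-population study design scaled to desk size:
    16 modern and 5 historical diploid genomes over a 30 Mb genome with one
    polymorphic site per kilobase.
    """

    seed: int = 0
    #: (name, length bp) per scaffold
    scaffolds: tuple[tuple[str, int], ...] = (
        ("scaf01", 10_000_000),
        ("scaf02", 10_000_000),
        ("scaf03", 10_000_000),
    )
    #: (name, n_modern, n_historical) per population
    populations: tuple[tuple[str, int, int], ...] = (
        ("Sumatra", 8, 0),
        ("Borneo", 5, 2),
        ("MalayPeninsula", 3, 3),
    )
    #: shape a of the symmetric Beta(a, a) for ancestral frequencies
    ancestral_beta: float = 0.5
    #: per-population Balding-Nichols drift parameter (expected F_ST scale)
    divergence_fst: Mapping[str, float] = field(
        default_factory=lambda: {"Sumatra": 0.1, "Borneo": 0.1, "MalayPeninsula": 0.1}
    )
    #: target inbreeding F per group; keys "Population" or "Population:era"
    inbreeding_f: Mapping[str, float] = field(default_factory=dict)
    #: IBD-tract length mixture: (weight, min bp, max bp), uniform within component
    roh_length_mix: tuple[tuple[float, int, int], ...] = (
        (0.6, 100_000, 1_000_000),
        (0.4, 1_000_000, 10_000_000),
    )
    n_sites: int = 30_000
    #: probabilities of (constrained > 4, intermediate, neutral < 1) GERP components
    gerp_mixture: tuple[float, float, float] = (0.2, 0.3, 0.5)
    #: fraction of SNP sites placed inside gene intervals
    coding_fraction: float = 0.3
    #: per-category probabilities (synonymous, missense, lof) for coding sites
    effect_probs: tuple[float, float, float] = (0.55, 0.4, 0.05)
    n_genes: int = 200
    gene_length: int = 20_000
    #: fraction of sites emitted as indel records (exercise the proximity filter)
    indel_fraction: float = 0.02
    #: per-sample mean coverage drawn uniformly from this interval
    coverage_range: tuple[float, float] = (9.0, 25.0)
    #: per-genotype missing rate
    missing_rate: float = 0.0
    #: fraction of sites written with the derived allele as REF (ancestral = ALT)
    aa_flip_fraction: float = 0.1
    #: fraction of the genome covered by the emitted repeat mask
    repeat_fraction: float = 0.02
    #: locus-specific drift overrides: (population, gene id, drift) — lets a
    #: single gene diverge in one population to plant a selection signal
    sweeps: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_sites > self.genome_length:
            raise ConfigError("n_sites exceeds genome length")
        for probs, label in (
            (self.gerp_mixture, "gerp_mixture"),
            (self.effect_probs, "effect_probs"),
        ):
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ConfigError(f"{label} must be probabilities summing to 1")
        for pop, f in self.divergence_fst.items():
            if not 0 <= f < 1:
                raise ConfigError(f"divergence_fst[{pop!r}] must be in [0, 1)")
        for key, f in self.inbreeding_f.items():
            if not 0 <= f <= 1:
                raise ConfigError(f"inbreeding_f[{key!r}] must be in [0, 1]")
        max_scaf = max(l for _, l in self.scaffolds)
        plants_tracts = any(f > 0 for f in self.inbreeding_f.values())
        for w, lo, hi in self.roh_length_mix:
            if lo > hi or lo < 1:
                raise ConfigError("invalid ROH length-mixture component")
            if plants_tracts and lo > max_scaf:
                raise ConfigError("ROH tract component longer than every scaffold")
        if not 0 <= self.coding_fraction <= 1:
            raise ConfigError("coding_fraction must be in [0, 1]")
        if round(self.n_sites * self.coding_fraction) > self.n_genes * self.gene_length:
            raise ConfigError("coding sites exceed total gene territory")

    @property
    def genome_length(self) -> int:
        return sum(l for _, l in self.scaffolds)

    def target_f(self, population: str, era: str) -> float:
        key = f"{population}:{era}"
        if key in self.inbreeding_f:
            return float(self.inbreeding_f[key])
        return float(self.inbreeding_f.get(population, 0.0))


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-condition config with selected fields overridden."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator.

    ``tracts``: planted IBD tracts (sample, chrom, start, end; 1-based
    inclusive).  ``true_f``: realized planted-tract fraction of the genome
    per sample.  ``pop_freqs``: per-site true derived-allele frequency per
    population (aligned with the dataset's site order).  ``site_labels``:
    per-site deleteriousness component (constrained / intermediate /
    neutral / indel).
    """

    tracts: pd.DataFrame
    true_f: pd.Series
    pop_freqs: pd.DataFrame
    site_labels: pd.Series
    genome_length: int

    def tracts_for(self, sample_id: str) -> pd.DataFrame:
        return self.tracts[self.tracts["sample"] == sample_id]


# ---------------------------------------------------------------------------
# ROH planting
# ---------------------------------------------------------------------------


def _check_tracts(
    tracts: Sequence[tuple[str, int, int]], scaffolds: Mapping[str, int]
) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in tracts:
        if chrom not in scaffolds:
            raise ConfigError(f"tract on unknown scaffold {chrom!r}")
        if start < 1 or end > scaffolds[chrom] or start > end:
            raise ConfigError(f"tract {chrom}:{start}-{end} outside scaffold bounds")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ConfigError(f"overlapping tracts on {chrom}: {s1}-{e1} and {s2}-{e2}")


def plant_roh(
    derived: np.ndarray,
    sites: pd.DataFrame,
    tracts: Mapping[int, Sequence[tuple[str, int, int]]],
    site_freq: np.ndarray,
    scaffolds: Mapping[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Force homozygosity inside planted IBD tracts.

    ``derived`` is a (sites x samples) derived-allele dosage matrix;
    ``tracts`` maps sample column index to its tract list; ``site_freq``
    gives each sample's population derived frequency per site (same shape as
    ``derived``).  Inside a tract the genotype becomes homozygous derived
    with probability equal to the site frequency, else homozygous ancestral.
    Sites outside tracts are untouched.  Overlapping or out-of-bounds tracts
    raise :class:`ConfigError`.
    """
    out = derived.copy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for col, tract_list in tracts.items():
        _check_tracts(tract_list, scaffolds)
        for chrom, start, end in tract_list:
            idx = np.flatnonzero((chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end))
            if idx.size == 0:
                continue
            hom_derived = rng.random(idx.size) < site_freq[idx, col]
            out[idx, col] = np.where(hom_derived, 2, 0)
    return out


def _draw_tracts(
    rng: np.random.Generator,
    scaffolds: Sequence[tuple[str, int]],
    target_f: float,
    mix: Sequence[tuple[float, int, int]],
) -> list[tuple[str, int, int]]:
    """Draw non-overlapping tracts totalling ~target_f of the genome.

    The target length is allocated to scaffolds proportionally; the last
    tract per scaffold is truncated so the realized total matches the target
    to within one minimum tract length.
    """
    weights = np.array([w for w, _, _ in mix], dtype=float)
    weights /= weights.sum()
    min_len = min(lo for _, lo, _ in mix)
    tracts: list[tuple[str, int, int]] = []
    for chrom, length in scaffolds:
        target = target_f * length
        lengths: list[int] = []
        total = 0
        while target - total >= min_len:
            k = rng.choice(len(mix), p=weights)
            l = int(rng.integers(mix[k][1], mix[k][2] + 1))
            l = min(l, int(target - total) if target - total >= min_len else l)
            l = min(l, int(0.95 * length) - total)
            if l < min_len:
                break
            lengths.append(l)
            total += l
        if not lengths:
            continue
        free = length - total
        cuts = np.sort(rng.random(len(lengths) + 1))
        gaps = np.floor(cuts / cuts.sum() * free).astype(int) if cuts.sum() > 0 else np.zeros(len(lengths) + 1, int)
        pos = 1
        for l, g in zip(lengths, gaps):
            start = pos + int(g)
            tracts.append((chrom, start, start + l - 1))
            pos = start + l
    return tracts


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _random_reference(rng: np.random.Generator, scaffolds) -> dict[str, str]:
    return {
        name: _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for name, length in scaffolds
    }


def _place_genes(rng, scaffolds, n_genes, gene_length) -> pd.DataFrame:
    """Non-overlapping gene intervals, allocated across scaffolds by length."""
    total = sum(l for _, l in scaffolds)
    counts = [int(round(n_genes * l / total)) for _, l in scaffolds]
    while sum(counts) < n_genes:
        counts[int(np.argmax([l for _, l in scaffolds]))] += 1
    while sum(counts) > n_genes:
        counts[int(np.argmax(counts))] -= 1
    rows = []
    gid = 0
    for (chrom, length), k in zip(scaffolds, counts):
        if k == 0:
            continue
        free = length - k * gene_length
        if free < 0:
            raise ConfigError(f"gene territory exceeds scaffold {chrom}")
        cuts = np.sort(rng.random(k + 1))
        gaps = np.floor(cuts / cuts.sum() * free).astype(int)
        pos = 1
        for g in gaps[:k]:
            start = pos + int(g)
            gid += 1
            rows.append((chrom, start, start + gene_length - 1, f"gene{gid:04d}"))
            pos = start + gene_length
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def _sample_positions(rng, intervals: list[tuple[str, int, int]], n: int) -> list[tuple[str, int]]:
    """Sample n unique positions uniformly from a set of disjoint intervals."""
    lens = np.array([e - s + 1 for _, s, e in intervals], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    total = int(offsets[-1])
    if n > total:
        raise ConfigError("more sites requested than available positions")
    flat = rng.choice(total, size=n, replace=False)
    flat.sort()
    idx = np.searchsorted(offsets, flat, side="right") - 1
    return [
        (intervals[i][0], int(intervals[i][1] + flat[j] - offsets[i]))
        for j, i in enumerate(idx)
    ]


def _complement(scaffolds, genes: pd.DataFrame) -> list[tuple[str, int, int]]:
    out = []
    for chrom, length in scaffolds:
        g = genes[genes["chrom"] == chrom].sort_values("start")
        pos = 1
        for _, row in g.iterrows():
            if row["start"] > pos:
                out.append((chrom, pos, row["start"] - 1))
            pos = row["end"] + 1
        if pos <= length:
            out.append((chrom, pos, length))
    return out


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[VariantDataset, SyntheticTruth, dict[str, Path] | None]:
    """Generate a full synthetic dataset (and optionally its file bundle).

    Returns the in-memory :class:`VariantDataset`, the ground truth, and —
    when ``out_dir`` is given — a dict of written file paths (reference
    FASTA, VCF, gene/repeat BEDs, GERP track, sample sheet, truth tables).
    Deterministic for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    scaffolds = list(config.scaffolds)
    scaf_len = dict(scaffolds)

    reference = _random_reference(rng, scaffolds)
    genes = _place_genes(rng, scaffolds, config.n_genes, config.gene_length)

    n_coding = int(round(config.n_sites * config.coding_fraction))
    gene_iv = [(r.chrom, r.start, r.end) for r in genes.itertuples()]
    coding_pos = _sample_positions(rng, gene_iv, n_coding) if n_coding else []
    noncoding_pos = _sample_positions(
        rng, _complement(scaffolds, genes), config.n_sites - n_coding
    )

    sites = pd.DataFrame(
        coding_pos + noncoding_pos, columns=["chrom", "pos"]
    )
    sites["coding"] = np.repeat([True, False], [len(coding_pos), len(noncoding_pos)])
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n = len(sites)

    # gene membership by interval overlap
    sites["gene"] = ""
    for r in genes.itertuples():
        hit = (sites["chrom"] == r.chrom) & (sites["pos"] >= r.start) & (sites["pos"] <= r.end)
        sites.loc[hit, "gene"] = r.gene

    # alleles from the reference base
    ref_codes = np.array(
        [reference[c][p - 1] for c, p in zip(sites["chrom"], sites["pos"])]
    )
    shift = rng.integers(1, 4, size=n)
    base_idx = np.array([b"ACGT".index(x.encode()) for x in ref_codes])
    alt_codes = np.array([chr(_BASES[(i + s) % 4]) for i, s in zip(base_idx, shift)])

    # ancestral frequencies and Balding-Nichols population frequencies
    a = config.ancestral_beta
    p0 = np.clip(rng.beta(a, a, size=n), 0.01, 0.99)
    pop_names = [p for p, _, _ in config.populations]
    freqs = {}
    for pop in pop_names:
        fst = config.divergence_fst.get(pop, 0.0)
        if fst <= 0:
            freqs[pop] = p0.copy()
        else:
            c = (1 - fst) / fst
            freqs[pop] = rng.beta(p0 * c, (1 - p0) * c)
    for pop, gene_id, fst in config.sweeps:
        idx = np.flatnonzero((sites["gene"] == gene_id).to_numpy())
        if idx.size == 0:
            raise ConfigError(f"sweep gene {gene_id!r} contains no sites")
        c = (1 - fst) / fst
        freqs[pop][idx] = rng.beta(p0[idx] * c, (1 - p0[idx]) * c)

    # samples: per population, modern then historical
    sample_rows = []
    for pop, n_mod, n_hist in config.populations:
        for i in range(n_mod):
            sample_rows.append((f"{pop}_mod{i + 1}", pop, "modern"))
        for i in range(n_hist):
            sample_rows.append((f"{pop}_hist{i + 1}", pop, "historical"))
    samples = pd.DataFrame(sample_rows, columns=["id", "population", "era"])
    samples["mean_coverage"] = np.round(
        rng.uniform(*config.coverage_range, size=len(samples)), 1
    )
    n_samp = len(samples)

    # derived-allele dosages from population frequencies
    derived = np.empty((n, n_samp), dtype=np.int8)
    site_freq = np.empty((n, n_samp), dtype=float)
    for j, row in samples.iterrows():
        q = freqs[row["population"]]
        site_freq[:, j] = q
        derived[:, j] = rng.binomial(2, q)

    # planted IBD tracts
    tract_map: dict[int, list[tuple[str, int, int]]] = {}
    tract_rows = []
    true_f = {}
    for j, row in samples.iterrows():
        f = config.target_f(row["population"], row["era"])
        tracts = _draw_tracts(rng, scaffolds, f, config.roh_length_mix) if f > 0 else []
        tract_map[j] = tracts
        planted = sum(e - s + 1 for _, s, e in tracts)
        true_f[row["id"]] = planted / config.genome_length
        tract_rows += [(row["id"], c, s, e) for c, s, e in tracts]
    derived = plant_roh(derived, sites, tract_map, site_freq, scaf_len, rng)

    # conservation scores and effect categories
    comp = rng.choice(3, size=n, p=config.gerp_mixture)
    gerp = np.where(
        comp == 0,
        rng.uniform(4.5, 6.5, size=n),
        np.where(comp == 1, rng.uniform(1.0, 4.0, size=n), rng.uniform(-3.0, 0.5, size=n)),
    )
    labels = np.array(["constrained", "intermediate", "neutral"])[comp].astype(object)

    effect = np.full(n, "none", dtype=object)
    coding_mask = sites["coding"].to_numpy()
    k_coding = int(coding_mask.sum())
    if k_coding:
        effect[coding_mask] = np.array(["synonymous", "missense", "lof"])[
            rng.choice(3, size=k_coding, p=config.effect_probs)
        ]

    # indels: drawn from non-coding sites, annotation-free
    is_indel = np.zeros(n, dtype=bool)
    n_indel = int(round(config.n_sites * config.indel_fraction))
    noncoding_idx = np.flatnonzero(~coding_mask)
    if n_indel and noncoding_idx.size:
        pick = rng.choice(noncoding_idx, size=min(n_indel, noncoding_idx.size), replace=False)
        is_indel[np.sort(pick)] = True
    gerp[is_indel] = np.nan
    labels[is_indel] = "indel"
    effect[is_indel] = "none"
    ins_base = _BASES[rng.integers(0, 4, size=n)]
    alt_out = np.where(
        is_indel,
        np.char.add(alt_codes.astype("U1"), np.char.decode(ins_base.astype("S1"))),
        alt_codes,
    )

    # polarization: a fraction of sites carry the derived allele as REF
    flip = rng.random(n) < config.aa_flip_fraction
    aa = np.where(flip, alt_out, ref_codes).astype(object)
    genotypes = np.where(flip[:, None], 2 - derived, derived).astype(np.int8)

    # per-genotype depth/quality and missingness
    mean_cov = samples["mean_coverage"].to_numpy()
    depth = rng.poisson(mean_cov[None, :], size=(n, n_samp)).astype(np.int32)
    qual = np.full((n, n_samp), 99, dtype=np.int32)
    if config.missing_rate > 0:
        genotypes[rng.random((n, n_samp)) < config.missing_rate] = MISSING

    site_frame = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "ref": ref_codes,
            "alt": alt_out,
            "is_indel": is_indel,
            "aa": aa,
            "gerp": gerp,
            "effect": effect,
            "gene": sites["gene"],
        }
    )
    data = VariantDataset(
        sites=site_frame, genotypes=genotypes, samples=samples, depth=depth, qual=qual
    )
    truth = SyntheticTruth(
        tracts=pd.DataFrame(tract_rows, columns=["sample", "chrom", "start", "end"]),
        true_f=pd.Series(true_f, name="true_f"),
        pop_freqs=pd.DataFrame(freqs),
        site_labels=pd.Series(labels, name="label"),
        genome_length=config.genome_length,
    )

    paths = None
    if out_dir is not None:
        paths = _write_bundle(Path(out_dir), config, reference, genes, data, truth, rng)
    return data, truth, paths


def _write_bundle(
    out_dir: Path,
    config: SimulationConfig,
    reference: Mapping[str, str],
    genes: pd.DataFrame,
    data: VariantDataset,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = out_dir / "reference.fa"
    with open(paths["reference"], "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    paths["vcf"] = out_dir / "variants.vcf"
    write_vcf(data, paths["vcf"], contigs=dict(config.scaffolds))

    paths["genes"] = out_dir / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for r in genes.itertuples():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\n")

    # repeat mask: random short intervals covering ~repeat_fraction of the genome
    paths["repeats"] = out_dir / "repeats.bed"
    with open(paths["repeats"], "w") as fh:
        for chrom, length in config.scaffolds:
            covered = 0
            target = config.repeat_fraction * length
            while covered < target:
                l = int(rng.integers(500, 5001))
                start = int(rng.integers(0, length - l))
                fh.write(f"{chrom}\t{start}\t{start + l}\n")
                covered += l

    paths["gerp"] = out_dir / "gerp.bed"
    with open(paths["gerp"], "w") as fh:
        for i in range(data.n_sites):
            row = data.sites.iloc[i]
            if not np.isnan(row["gerp"]):
                fh.write(f"{row['chrom']}\t{row['pos'] - 1}\t{row['pos']}\t{row['gerp']:.3f}\n")

    paths["samples"] = out_dir / "samples.tsv"
    data.samples.to_csv(paths["samples"], sep="\t", index=False)

    paths["truth_tracts"] = out_dir / "truth_tracts.tsv"
    truth.tracts.to_csv(paths["truth_tracts"], sep="\t", index=False)
    paths["truth_f"] = out_dir / "truth_f.tsv"
    truth.true_f.rename_axis("sample").to_csv(paths["truth_f"], sep="\t")
    paths["truth_freqs"] = out_dir / "truth_freqs.tsv"
    truth.pop_freqs.round(6).to_csv(paths["truth_freqs"], sep="\t", index=False)
    paths["truth_labels"] = out_dir / "truth_labels.tsv"
    truth.site_labels.to_csv(paths["truth_labels"], sep="\t", index=False)
    return paths
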