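"""Shared variant data model, standard-format I/O and site filtering.

The central container is :class:`VariantDataset`: a sites x samples matrix of
alternate-allele dosages with per-site annotations (ancestral allele,
conservation score, effect category, gene id) and per-sample metadata
(population, era, mean sequencing coverage).  Downstream analyses of derived
alleles polarize dosages with the recorded ancestral allele; sites where the
ancestral state is unknown stay usable for heterozygosity and runs of
homozygosity but are excluded from derived-allele computations.

Filtering follows the conventions of low-sample-size resequencing studies of
endangered populations: per-genotype depth below one third of the sample's
mean coverage or genotype quality below 30 sets the call to missing; SNPs
within +/- 5 bp of an indel, CpG sites, repeat regions and sex-linked
scaffolds are removed outright.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EFFECT_CATEGORIES",
    "MISSING",
    "VariantDataset",
    "SiteMask",
    "FilterReport",
    "find_cpg_sites",
    "apply_site_filters",
    "read_vcf",
    "write_vcf",
    "read_sample_metadata",
    "read_bed_intervals",
    "read_gerp_bed",
    "read_fasta",
]

#: Valid effect-category labels for coding annotation.
EFFECT_CATEGORIES = ("none", "synonymous", "missense", "lof")

#: Sentinel for a missing genotype in the dosage matrix.
MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "is_indel", "aa", "gerp", "effect", "gene"]


def _as_site_frame(sites: pd.DataFrame) -> pd.DataFrame:
    out = sites.copy().reset_index(drop=True)
    for col in SITE_COLUMNS:
        if col not in out.columns:
            if col == "is_indel":
                out[col] = False
            elif col == "gerp":
                out[col] = np.nan
            elif col == "effect":
                out[col] = "none"
            else:
                out[col] = ""
    out["pos"] = out["pos"].astype(np.int64)
    out["is_indel"] = out["is_indel"].astype(bool)
    out["gerp"] = out["gerp"].astype(float)
    return out[SITE_COLUMNS]


@dataclass
class VariantDataset:
    """Sites x samples alternate-allele dosage matrix with annotations.

    Parameters
    ----------
    sites
        One row per site, columns ``chrom, pos, ref, alt, is_indel, aa,
        gerp, effect, gene``.  ``pos`` is 1-based; rows sorted by
        ``(chrom, pos)``.  ``aa`` is the ancestral allele string or ``""``
        when unknown.
    genotypes
        ``(n_sites, n_samples)`` int8 array of alternate-allele dosages in
        ``{0, 1, 2}`` with :data:`MISSING` for no-calls.
    samples
        One row per sample, columns ``id, population, era, mean_coverage``.
    depth, qual
        Optional per-genotype depth / genotype-quality arrays with the same
        shape as ``genotypes``; required only for genotype-level filtering.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: pd.DataFrame
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = _as_site_frame(self.sites)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(len(self.sites))):
            raise ValueError("sites must be sorted by (chrom, pos)")
        for arr_name in ("depth", "qual"):
            arr = getattr(self, arr_name)
            if arr is not None and np.asarray(arr).shape != self.genotypes.shape:
                raise ValueError(f"{arr_name} shape does not match genotypes")

    # -- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["id"])

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero((self.samples["id"] == sample_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return int(idx[0])

    def population_mask(self, population: str, era: str | None = None) -> np.ndarray:
        mask = (self.samples["population"] == population).to_numpy()
        if era is not None:
            mask &= (self.samples["era"] == era).to_numpy()
        return mask

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    # -- derived-allele polarization ------------------------------------

    def derived_dosage(self) -> np.ndarray:
        """Per-genotype derived-allele dosage as float, NaN where undefined.

        Undefined means: missing genotype, or ancestral allele unknown /
        matching neither REF nor ALT.
        """
        aa = self.sites["aa"].to_numpy()
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        gt = self.genotypes.astype(np.float64)
        gt[self.genotypes == MISSING] = np.nan
        anc_is_ref = aa == ref
        anc_is_alt = aa == alt
        out = np.full_like(gt, np.nan)
        out[anc_is_ref, :] = gt[anc_is_ref, :]
        out[anc_is_alt, :] = 2.0 - gt[anc_is_alt, :]
        return out

    def derived_allele_counts(self, sample_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Derived allele count and total called allele number per site.

        Sites with unknown ancestral allele get allele number 0.
        """
        dd = self.derived_dosage()[:, sample_mask]
        called = ~np.isnan(dd)
        ac = np.nansum(dd, axis=1)
        an = 2 * called.sum(axis=1)
        return ac, an

    def derived_allele_freq(self, sample_mask: np.ndarray) -> np.ndarray:
        """Per-site derived-allele frequency over non-missing calls (NaN if none)."""
        ac, an = self.derived_allele_counts(sample_mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    def alt_allele_counts(self, sample_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Alternate allele count and called allele number per site (no polarization)."""
        gt = self.genotypes[:, sample_mask]
        called = gt != MISSING
        ac = np.where(called, gt, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        return ac.astype(float), an.astype(float)

    def subset_sites(self, keep: np.ndarray) -> "VariantDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantDataset(
            sites=self.sites.iloc[keep],
            genotypes=self.genotypes[keep],
            samples=self.samples,
            depth=None if self.depth is None else self.depth[keep],
            qual=None if self.qual is None else self.qual[keep],
        )

    def equals(self, other: "VariantDataset") -> bool:
        return (
            self.sites.equals(other.sites)
            and np.array_equal(self.genotypes, other.genotypes)
            and self.samples.equals(other.samples)
        )


# ---------------------------------------------------------------------------
# Site masks
# ---------------------------------------------------------------------------


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 1-based inclusive intervals, sorted output."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass(frozen=True)
class SiteMask:
    """Positions to exclude, stored as merged per-scaffold intervals.

    Intervals are 1-based inclusive.  ``excluded_scaffolds`` drop every site
    on those scaffolds (e.g. sex-linked scaffolds).
    """

    intervals: Mapping[str, np.ndarray] = field(default_factory=dict)
    excluded_scaffolds: frozenset[str] = frozenset()

    @classmethod
    def from_positions(cls, positions: Mapping[str, Iterable[int]]) -> "SiteMask":
        iv = {}
        for chrom, pos in positions.items():
            p = np.unique(np.asarray(list(pos), dtype=np.int64))
            if p.size:
                iv[chrom] = _merge_intervals(np.column_stack([p, p]))
        return cls(intervals=iv)

    @classmethod
    def from_bed(cls, path: str | Path) -> "SiteMask":
        """Read a BED (0-based half-open) mask, converting to 1-based inclusive."""
        rows: dict[str, list[list[int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                rows.setdefault(chrom, []).append([int(start) + 1, int(end)])
        iv = {c: _merge_intervals(np.asarray(v, dtype=np.int64)) for c, v in rows.items()}
        return cls(intervals=iv)

    def union(self, other: "SiteMask") -> "SiteMask":
        chroms = set(self.intervals) | set(other.intervals)
        iv = {}
        for c in chroms:
            parts = [x for x in (self.intervals.get(c), other.intervals.get(c)) if x is not None and len(x)]
            iv[c] = _merge_intervals(np.vstack(parts))
        return SiteMask(
            intervals=iv,
            excluded_scaffolds=self.excluded_scaffolds | other.excluded_scaffolds,
        )

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``pos`` (1-based) fall in a masked interval."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom in self.excluded_scaffolds:
            return np.ones(pos.shape, dtype=bool)
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos[inside] <= iv[idx[inside], 1]
        return inside

    def n_masked_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0] + 1).sum() for iv in self.intervals.values()))


def find_cpg_sites(reference: Mapping[str, str]) -> SiteMask:
    """Locate CpG dinucleotides: every C immediately followed by a G.

    Both positions of each CG pair are masked (1-based).  Matching is
    case-insensitive; ambiguous bases (N etc.) never match.
    """
    intervals: dict[str, np.ndarray] = {}
    for chrom, seq in reference.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        if arr.size < 2:
            continue
        start = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if start.size:
            # CG at 0-based i covers 1-based positions i+1, i+2
            intervals[chrom] = _merge_intervals(
                np.column_stack([start + 1, start + 2]).astype(np.int64)
            )
    return SiteMask(intervals=intervals)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`apply_site_filters`."""

    n_sites_in: int = 0
    n_sites_out: int = 0
    genotypes_set_missing_depth: int = 0
    genotypes_set_missing_qual: int = 0
    sites_removed_indel: int = 0
    sites_removed_near_indel: int = 0
    sites_removed_masked: int = 0
    sites_removed_excluded_scaffold: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(vars(self)), "count": list(vars(self).values())}
        )


def apply_site_filters(
    data: VariantDataset,
    mask: SiteMask | None = None,
    *,
    min_gq: float = 30.0,
    depth_fraction: float = 1.0 / 3.0,
    indel_window: int = 5,
    exclude_scaffolds: Sequence[str] = (),
) -> tuple[VariantDataset, FilterReport]:
    """Apply the study-style site and genotype filters.

    Genotype level (only when depth / quality matrices are present): a call
    with depth below ``depth_fraction`` of its sample's mean coverage, or
    genotype quality below ``min_gq``, is set to missing.  Site level: indel
    records are dropped from the SNP table, SNPs within ``indel_window`` bp
    (inclusive) of an indel are removed, as are masked positions and sites on
    excluded scaffolds.  Retained genotype values are never altered, so the
    operation is idempotent.
    """
    report = FilterReport(n_sites_in=data.n_sites)
    gt = data.genotypes.copy()

    if data.depth is not None:
        cov = data.samples["mean_coverage"].to_numpy(dtype=float)
        bad = np.isnan(cov)
        if bad.any():
            name = data.samples["id"].iloc[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"mean coverage missing for sample {name!r}; required for depth filtering")
        thr = cov * depth_fraction  # per-sample threshold, broadcast over sites
        fail = (data.depth < thr[None, :]) & (gt != MISSING)
        report.genotypes_set_missing_depth = int(fail.sum())
        gt[fail] = MISSING
    if data.qual is not None:
        fail = (data.qual < min_gq) & (gt != MISSING)
        report.genotypes_set_missing_qual = int(fail.sum())
        gt[fail] = MISSING

    sites = data.sites
    keep = np.ones(data.n_sites, dtype=bool)

    is_indel = sites["is_indel"].to_numpy()
    # SNPs within +/- indel_window bp (inclusive) of any indel position
    near = np.zeros(data.n_sites, dtype=bool)
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ind = pos[is_indel[grp.index.to_numpy()]]
        if ind.size == 0:
            continue
        lo = np.searchsorted(ind, pos - indel_window, side="left")
        hi = np.searchsorted(ind, pos + indel_window, side="right")
        near[grp.index.to_numpy()] = hi > lo
    near &= ~is_indel
    report.sites_removed_near_indel = int(near.sum())
    report.sites_removed_indel = int(is_indel.sum())
    keep &= ~near
    keep &= ~is_indel

    excl = set(exclude_scaffolds)
    if mask is not None:
        excl |= set(mask.excluded_scaffolds)
        masked = np.zeros(data.n_sites, dtype=bool)
        for chrom, grp in sites.groupby("chrom", sort=False):
            masked[grp.index.to_numpy()] = mask.contains(chrom, grp["pos"].to_numpy())
        masked &= keep
        # scaffold exclusion is counted separately below
        on_excl = sites["chrom"].isin(excl).to_numpy()
        report.sites_removed_masked = int((masked & ~on_excl).sum())
        keep &= ~(masked & ~on_excl)
    if excl:
        on_excl = sites["chrom"].isin(excl).to_numpy() & keep
        report.sites_removed_excluded_scaffold = int(on_excl.sum())
        keep &= ~on_excl

    out = VariantDataset(
        sites=sites.loc[keep],
        genotypes=gt[keep],
        samples=data.samples,
        depth=None if data.depth is None else data.depth[keep],
        qual=None if data.qual is None else data.qual[keep],
    )
    report.n_sites_out = out.n_sites
    return out, report


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns id, population, era, mean_coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "population": str, "era": str})
    required = {"id", "population", "era", "mean_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return df


def read_bed_intervals(path: str | Path, name_col: str = "gene") -> pd.DataFrame:
    """Read a BED file into a frame with 1-based inclusive start/end."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"iv{len(rows)}"
            rows.append((parts[0], int(parts[1]) + 1, int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", name_col])


def read_gerp_bed(path: str | Path) -> pd.DataFrame:
    """Read a per-position conservation-score track (BED-like TSV with a score column)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"] + 1  # to 1-based inclusive
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA reference into memory as {scaffold: sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, read_ahead=10_000_000)
    return {name: str(fa[name][:]) for name in fa.keys()}


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=GERP,Number=1,Type=Float,Description="Conservation (GERP) score">
##INFO=<ID=EFF,Number=1,Type=String,Description="Effect category: synonymous/missense/lof/none">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    data: VariantDataset,
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write the dataset as a plain-text VCF v4.2 with AA/GERP/EFF/GENE INFO keys.

    Output is byte-deterministic for identical inputs.
    """
    sites = data.sites
    gt = data.genotypes
    dp = data.depth
    gq = data.qual
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.sample_ids)
            + "\n"
        )
        fmt = "GT" + (":DP" if dp is not None else "") + (":GQ" if gq is not None else "")
        for i in range(data.n_sites):
            row = sites.iloc[i]
            info = []
            if row["aa"]:
                info.append(f"AA={row['aa']}")
            if not np.isnan(row["gerp"]):
                info.append(f"GERP={row['gerp']:.3f}")
            if row["effect"] and row["effect"] != "none":
                info.append(f"EFF={row['effect']}")
            if row["gene"]:
                info.append(f"GENE={row['gene']}")
            cells = []
            for j in range(data.n_samples):
                cell = _GT_STR[int(gt[i, j])]
                if dp is not None:
                    cell += f":{int(dp[i, j])}"
                if gq is not None:
                    cell += f":{int(gq[i, j])}"
                cells.append(cell)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t"
                + (";".join(info) if info else ".")
                + f"\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path, metadata: pd.DataFrame | str | Path) -> VariantDataset:
    """Read a (plain or bgzipped) VCF into a :class:`VariantDataset`.

    ``metadata`` is the sample sheet (frame or TSV path); its rows are
    reordered to match the VCF sample order and every VCF sample must be
    present in it.
    """
    from cyvcf2 import VCF

    if not isinstance(metadata, pd.DataFrame):
        metadata = read_sample_metadata(metadata)

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    meta = metadata.set_index("id")
    missing = [s for s in vcf_samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples in VCF but not in metadata: {missing}")
    samples = meta.loc[vcf_samples].reset_index()

    rows, gts, dps, gqs = [], [], [], []
    have_dp = have_gq = True
    for v in vcf:
        alt = v.ALT[0] if v.ALT else ""
        is_indel = len(v.REF) != 1 or len(alt) != 1
        aa = v.INFO.get("AA") or ""
        gerp = v.INFO.get("GERP")
        eff = v.INFO.get("EFF") or "none"
        gene = v.INFO.get("GENE") or ""
        rows.append(
            (v.CHROM, v.POS, v.REF, alt, is_indel, aa,
             np.nan if gerp is None else float(gerp), eff, gene)
        )
        g = v.gt_types.astype(np.int8)  # gts012: 0,1,2 dosage; 3 unknown
        g[g == 3] = MISSING
        gts.append(g)
        if have_dp:
            d = v.format("DP")
            if d is None:
                have_dp = False
            else:
                dps.append(d[:, 0].astype(np.int32))
        if have_gq:
            q = v.format("GQ")
            if q is None:
                have_gq = False
            else:
                gqs.append(q[:, 0].astype(np.int32))

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n = len(sites)
    gt = np.vstack(gts) if n else np.empty((0, len(vcf_samples)), dtype=np.int8)
    return VariantDataset(
        sites=sites,
        genotypes=gt,
        samples=samples,
        depth=np.vstack(dps) if (have_dp and dps and len(dps) == n) else None,
        qual=np.vstack(gqs) if (have_gq and gqs and len(gqs) == n) else None,
    )
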