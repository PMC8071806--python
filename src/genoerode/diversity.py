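"""Per-individual genome-wide heterozygosity and runs of homozygosity.

Heterozygosity is reported as heterozygous sites per 1000 bp of callable
genome (the field's θ convention for genotype-based estimates).  Runs of
homozygosity (ROH) are called with a sliding-window heterozygote-density
scan; the genomic inbreeding coefficient F_ROH is the fraction of the genome
contained in ROH above a length threshold, conventionally reported at
>= 100 kb (all ROH) and >= 2 Mb (recent inbreeding).

ROH algorithm
-------------
Per scaffold, the sample's non-missing genotypes are scanned left to right.
A run starts at a homozygous site and is extended one site at a time while
two conditions hold: (1) every window of ``window_snps`` consecutive sites
inside the run (the whole run while it is shorter) contains at most
``max_het_per_window`` heterozygous calls, and (2) consecutive sites are at
most ``max_gap`` bp apart.  When extension stops, the run is trimmed to its
outermost homozygous sites and reported if it spans at least ``min_length``
bp and ``min_snps`` sites; the scan resumes after the run.  The procedure is
deterministic and greedy, so per-sample segments never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, VariantDataset

__all__ = [
    "HeterozygosityResult",
    "ROHParams",
    "ROHSegment",
    "ROHSummary",
    "genome_heterozygosity",
    "detect_roh",
    "froh",
    "roh_summary",
]


@dataclass(frozen=True)
class HeterozygosityResult:
    sample_id: str
    het_sites: int
    callable_length: int
    theta: float  # het sites per 1000 bp


@dataclass(frozen=True)
class ROHParams:
    """Thresholds of the sliding-window ROH scan (defaults for ~1 SNP/kb data)."""

    window_snps: int = 50
    max_het_per_window: int = 1
    min_length: int = 100_000
    min_snps: int = 25
    max_gap: int = 500_000

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("window_snps and min_snps must be >= 1")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive, position of first homozygous SNP
    end: int  # 1-based inclusive, position of last homozygous SNP
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ROHSummary:
    sample_id: str
    froh_100kb: float
    froh_2mb: float
    genome_length: int
    n_segments: int


def genome_heterozygosity(
    data: VariantDataset, sample_id: str, callable_length: int
) -> HeterozygosityResult:
    """Heterozygous-site density for one sample.

    ``callable_length`` is the number of filtered-callable positions in the
    genome (all positions passing the site filters, not just variant sites);
    missing genotypes never enter the numerator.
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be > 0")
    j = data.sample_index(sample_id)
    het = int((data.genotypes[:, j] == 1).sum())
    return HeterozygosityResult(
        sample_id=sample_id,
        het_sites=het,
        callable_length=callable_length,
        theta=1000.0 * het / callable_length,
    )


def _scan_scaffold(
    sample_id: str,
    chrom: str,
    pos: np.ndarray,
    het: np.ndarray,
    p: ROHParams,
) -> list[ROHSegment]:
    """Greedy left-to-right run extension over one scaffold's called sites."""
    n = pos.size
    segs: list[ROHSegment] = []
    hom = ~het
    cum = np.concatenate([[0], np.cumsum(het)])  # prefix het counts
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            k = j + 1
            if pos[k] - pos[j] > p.max_gap:
                break
            w_start = max(i, k - p.window_snps + 1)
            if cum[k + 1] - cum[w_start] > p.max_het_per_window:
                break
            j = k
        # trim to last homozygous site in [i, j]
        e = j
        while e > i and not hom[e]:
            e -= 1
        if hom[e]:
            length = int(pos[e] - pos[i] + 1)
            if length >= p.min_length and (e - i + 1) >= p.min_snps:
                segs.append(
                    ROHSegment(sample_id, chrom, int(pos[i]), int(pos[e]), e - i + 1)
                )
        i = j + 1
    return segs


def detect_roh(
    data: VariantDataset, sample_id: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call ROH segments for one sample (see module docstring for the rule)."""
    p = params or ROHParams()
    j = data.sample_index(sample_id)
    gt = data.genotypes[:, j]
    called = gt != MISSING
    segs: list[ROHSegment] = []
    chroms = data.sites["chrom"].to_numpy()
    pos_all = data.sites["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        m = (chroms == chrom) & called
        segs += _scan_scaffold(sample_id, chrom, pos_all[m], gt[m] == 1, p)
    return segs


def froh(
    segments: Sequence[ROHSegment], genome_length: int, min_length: int
) -> float:
    """Fraction of the genome in segments at least ``min_length`` bp long."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append((s.start, s.end))
    for ivs in by_key.values():
        ivs.sort()
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping ROH segments: {s1}-{e1} and start {s2}")
    return sum(s.length for s in segments if s.length >= min_length) / genome_length


def roh_summary(
    data: VariantDataset,
    sample_id: str,
    genome_length: int,
    params: ROHParams | None = None,
) -> ROHSummary:
    """Detect ROH and summarize F_ROH at the 100 kb and 2 Mb thresholds."""
    segs = detect_roh(data, sample_id, params)
    return ROHSummary(
        sample_id=sample_id,
        froh_100kb=froh(segs, genome_length, 100_000),
        froh_2mb=froh(segs, genome_length, 2_000_000),
        genome_length=genome_length,
        n_segments=len(segs),
    )


def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.end, s.length, s.n_snps) for s in segments],
        columns=["sample", "chrom", "start", "end", "length", "n_snps"],
    )
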