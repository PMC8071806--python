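"""Shared test helpers: compact dataset construction and the brute-force ROH oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd

from genoerode.diversity import ROHParams
from genoerode.variant_io import VariantDataset


def make_dataset(
    gt,
    *,
    pos=None,
    chrom="s1",
    populations=None,
    era=None,
    aa=None,
    gerp=None,
    effect=None,
    gene=None,
    ref=None,
    alt=None,
    is_indel=None,
    mean_coverage=20.0,
    depth=None,
    qual=None,
) -> VariantDataset:
    """Build a small VariantDataset from a (sites x samples) dosage matrix.

    Defaults: REF A / ALT C, ancestral = REF (so alt dosage is derived
    dosage), positions 1..n on one scaffold, all samples in population "P",
    era "modern".
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    pos = np.arange(1, n_sites + 1) if pos is None else np.asarray(pos)
    chrom_arr = np.full(n_sites, chrom) if isinstance(chrom, str) else np.asarray(chrom)
    ref = np.full(n_sites, "A") if ref is None else np.asarray(ref, dtype=object)
    alt = np.full(n_sites, "C") if alt is None else np.asarray(alt, dtype=object)
    aa = ref.copy() if aa is None else np.asarray(aa, dtype=object)
    sites = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "is_indel": np.zeros(n_sites, bool) if is_indel is None else is_indel,
            "aa": aa,
            "gerp": np.full(n_sites, np.nan) if gerp is None else np.asarray(gerp, float),
            "effect": np.full(n_sites, "none", dtype=object) if effect is None else effect,
            "gene": np.full(n_sites, "", dtype=object) if gene is None else gene,
        }
    )
    populations = ["P"] * n_samples if populations is None else list(populations)
    era = ["modern"] * n_samples if era is None else list(era)
    samples = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n_samples)],
            "population": populations,
            "era": era,
            "mean_coverage": np.broadcast_to(np.asarray(mean_coverage, float), (n_samples,)).copy(),
        }
    )
    return VariantDataset(
        sites=sites, genotypes=gt, samples=samples,
        depth=None if depth is None else np.asarray(depth),
        qual=None if qual is None else np.asarray(qual),
    )


def _window_valid(pos, cum_het, i, j, p: ROHParams) -> bool:
    """Exhaustively verify every window condition and gap for run [i, j]."""
    if j > i and np.any(np.diff(pos[i : j + 1]) > p.max_gap):
        return False
    length = j - i + 1
    w = min(p.window_snps, length)
    window_sums = cum_het[i + w : j + 2] - cum_het[i : j + 2 - w]
    return int(window_sums.max()) <= p.max_het_per_window


def roh_oracle(pos, het, params: ROHParams, sample_id="s0", chrom="s1"):
    """Brute-force ROH caller: greedy left-to-right extension, with the
    run-validity conditions re-verified exhaustively (all windows, all gaps)
    at every extension step instead of incrementally.

    Returns (start, end, n_snps) tuples over the called (non-missing) sites.
    """
    pos = np.asarray(pos)
    het = np.asarray(het, dtype=bool)
    cum = np.concatenate([[0], np.cumsum(het)])
    n = pos.size
    segs = []
    i = 0
    while i < n:
        if het[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and _window_valid(pos, cum, i, j + 1, params):
            j += 1
        e = j
        while e > i and het[e]:
            e -= 1
        if not het[e]:
            if pos[e] - pos[i] + 1 >= params.min_length and e - i + 1 >= params.min_snps:
                segs.append((int(pos[i]), int(pos[e]), e - i + 1))
        i = j + 1
    return segs
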