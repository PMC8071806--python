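"""Group comparisons and end-to-end pipeline orchestration.

Population and era contrasts use unadjusted two-sided pairwise Welch
t-tests — the convention for per-individual genomic summary statistics at
n of a few samples per group — together with the two descriptive effect
measures used throughout this kind of study: signed percent difference
100·(a - b)/b and fold change modern/historical.

``run_pipeline`` chains filtering, diversity, GERP load, coding burden,
selection scan and the group comparisons over a config of input paths, and
writes one TSV per stage plus a combined JSON summary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import coding_load, diversity, gerp_load, selection, variant_io

__all__ = [
    "GroupComparison",
    "pairwise_t_tests",
    "percent_difference",
    "fold_change",
    "run_pipeline",
]

log = logging.getLogger("genoerode")


@dataclass(frozen=True)
class GroupComparison:
    statistic: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p_value: float
    fold_change: float  # mean_b / mean_a
    percent_difference: float  # 100 * (mean_a - mean_b) / mean_b


def pairwise_t_tests(
    values: pd.Series,
    groups: pd.Series,
    statistic: str = "statistic",
    *,
    equal_var: bool = False,
) -> list[GroupComparison]:
    """Unadjusted two-sided pairwise t-tests (Welch by default) between groups.

    ``values`` holds the per-sample statistic, ``groups`` the group label per
    sample (aligned index).  Group pairs with fewer than two samples on
    either side are skipped with a warning.  No multiple-testing adjustment
    is applied.
    """
    out: list[GroupComparison] = []
    labels = list(dict.fromkeys(groups))
    for ga, gb in combinations(labels, 2):
        va = values[groups == ga].to_numpy(dtype=float)
        vb = values[groups == gb].to_numpy(dtype=float)
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(
                f"skipping {ga} vs {gb} for {statistic}: fewer than 2 samples in a group",
                stacklevel=2,
            )
            continue
        if np.allclose(va, vb[0]) and np.allclose(vb, vb[0]):
            t, p = 0.0, 1.0  # identical constant vectors: no evidence of difference
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        out.append(
            GroupComparison(
                statistic=statistic,
                group_a=str(ga),
                group_b=str(gb),
                n_a=len(va),
                n_b=len(vb),
                mean_a=mean_a,
                mean_b=mean_b,
                sd_a=float(va.std(ddof=1)),
                sd_b=float(vb.std(ddof=1)),
                t=float(t),
                p_value=float(p),
                fold_change=float(mean_b / mean_a) if mean_a != 0 else float("nan"),
                percent_difference=(
                    100.0 * (mean_a - mean_b) / mean_b if mean_b != 0 else float("nan")
                ),
            )
        )
    return out


def percent_difference(a: float, b: float) -> float:
    """Signed percent difference of a relative to b: 100·(a - b)/b."""
    if b == 0:
        raise ValueError("reference mean b must be non-zero")
    return 100.0 * (a - b) / b


def fold_change(modern: float, historical: float) -> float:
    """Fold change of a statistic between eras: modern / historical."""
    if historical <= 0:
        raise ValueError("historical mean must be > 0")
    return modern / historical


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in comparisons])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, 10)
    return obj


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run filter → diversity → GERP load → coding burden → selection → comparisons.

    ``config`` is a mapping (or YAML path) with keys::

        vcf, metadata, genome_length          # required
        reference, repeats_bed, genes_bed     # optional inputs
        exclude_scaffolds: [..]               # optional
        gerp: {threshold: 4.0}                # optional settings
        sharing: {seed: 0, n_alleles: 6}
        pbs: {threshold: 3.0, percentile: 99.8}
        roh: {window_snps: .., min_length: ..}
        out_dir

    Stages needing an absent input are skipped with an explicit notice.
    Writes one TSV per stage and ``summary.json``; deterministic given the
    config (the only stochastic stage, allele sharing, takes its seed from
    the config).
    """
    if not isinstance(config, Mapping):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "skipped": []}

    meta = variant_io.read_sample_metadata(config["metadata"])
    data = variant_io.read_vcf(config["vcf"], meta)
    genome_length = int(config["genome_length"])

    # -- filtering -------------------------------------------------------
    mask = None
    if config.get("reference"):
        ref = variant_io.read_fasta(config["reference"])
        mask = variant_io.find_cpg_sites(ref)
    if config.get("repeats_bed"):
        rep = variant_io.SiteMask.from_bed(config["repeats_bed"])
        mask = rep if mask is None else mask.union(rep)
    data, report = variant_io.apply_site_filters(
        data, mask, exclude_scaffolds=config.get("exclude_scaffolds", ())
    )
    report.to_frame().to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
    summary["stages"]["filter"] = {k: int(v) for k, v in vars(report).items()}
    log.info("filter: %d -> %d sites", report.n_sites_in, report.n_sites_out)

    # -- diversity -------------------------------------------------------
    roh_params = diversity.ROHParams(**config.get("roh", {}))
    div_rows = []
    all_segments = []
    for _, s in data.samples.iterrows():
        het = diversity.genome_heterozygosity(data, s["id"], genome_length)
        segs = diversity.detect_roh(data, s["id"], roh_params)
        all_segments += segs
        div_rows.append(
            (
                s["id"], s["population"], s["era"], het.theta,
                diversity.froh(segs, genome_length, 100_000),
                diversity.froh(segs, genome_length, 2_000_000),
            )
        )
    div = pd.DataFrame(
        div_rows, columns=["sample", "population", "era", "theta", "froh_100kb", "froh_2mb"]
    )
    div.to_csv(out_dir / "diversity.tsv", sep="\t", index=False, float_format="%.6f")
    seg_frame = diversity.segments_to_frame(all_segments)
    with open(out_dir / "roh.bed", "w") as fh:
        for r in seg_frame.itertuples():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.sample}\n")
    summary["stages"]["diversity"] = {
        "n_samples": int(len(div)),
        "n_roh_segments": int(len(seg_frame)),
        "mean_theta": float(div["theta"].mean()),
        "mean_froh_100kb": float(div["froh_100kb"].mean()),
    }

    # -- GERP load -------------------------------------------------------
    has_gerp = bool(np.isfinite(data.sites["gerp"]).any())
    if has_gerp:
        thr = float(config.get("gerp", {}).get("threshold", 4.0))
        loads = gerp_load.load_table(data, thr)
        loads.to_csv(out_dir / "gerp_load.tsv", sep="\t", index=False, float_format="%.6f")
        share_cfg = config.get("sharing", {})
        modern_pops = [
            p for p in data.populations()
            if (data.population_mask(p, "modern")).sum() >= 3
        ]
        sharing = None
        if len(modern_pops) >= 2:
            sharing = gerp_load.allele_sharing(
                data, modern_pops,
                n_alleles=int(share_cfg.get("n_alleles", 6)),
                score_threshold=thr,
                seed=int(share_cfg.get("seed", 0)),
            )
            pd.Series(sharing.percent).rename_axis("category").rename("percent").to_csv(
                out_dir / "allele_sharing.tsv", sep="\t", float_format="%.4f"
            )
        summary["stages"]["gerp_load"] = {
            "threshold": thr,
            "mean_relative_load": float(loads["relative_load"].mean()),
            "sharing": None if sharing is None else {
                "percent": sharing.percent, "n_sites_used": sharing.n_sites_used
            },
        }
    else:
        summary["skipped"].append("gerp_load: no conservation scores in input")
        log.info("gerp_load skipped: no conservation scores")
        loads = None

    # -- coding burden ---------------------------------------------------
    has_effects = bool((data.sites["effect"] != "none").any())
    if has_effects:
        btab = coding_load.burden_table(data)
        btab.to_csv(out_dir / "burden.tsv", sep="\t", index=False)
        risk_rows = []
        pops = data.populations()
        for _, s in data.samples.iterrows():
            for pop in pops:
                if pop == s["population"]:
                    continue
                n, _ = coding_load.translocation_risk(data, s["id"], pop)
                risk_rows.append((s["id"], s["population"], pop, n))
        pd.DataFrame(
            risk_rows, columns=["donor", "donor_population", "recipient_population", "n_novel_lof"]
        ).to_csv(out_dir / "translocation_risk.tsv", sep="\t", index=False)
        pop_sums = {p: coding_load.population_summary(data, p) for p in pops}
        summary["stages"]["coding_load"] = {
            p: {
                "n_lof_sites": s.n_lof_sites,
                "n_genes_with_lof": s.n_genes_with_lof,
                "n_fixed": int(s.fixed_sites.size),
                "n_private": int(s.private_sites.size),
                "n_private_and_fixed": int(s.private_and_fixed_sites.size),
            }
            for p, s in pop_sums.items()
        }
    else:
        summary["skipped"].append("coding_load: no effect annotations in input")
        btab = None

    # -- selection -------------------------------------------------------
    pops = data.populations()
    if config.get("genes_bed") and has_effects and len(pops) == 3:
        genes = variant_io.read_bed_intervals(config["genes_bed"])
        scan = selection.pbs_scan(data, genes, pops)
        scan.to_csv(out_dir / "pbs.tsv", sep="\t", index=False, float_format="%.6f")
        pbs_cfg = config.get("pbs", {})
        calls = selection.cap_and_call(
            scan, pops,
            threshold=float(pbs_cfg.get("threshold", 3.0)),
            percentile=float(pbs_cfg.get("percentile", 99.8)),
        )
        mis = selection.missense_summary(data, pops)
        summary["stages"]["selection"] = {
            "n_genes_scanned": int((~scan["no_data"]).sum()),
            "outliers": {p: sorted(calls.outliers[p]) for p in pops},
            "unique_outliers": {p: calls.unique_outliers[p] for p in pops},
            "percentile_value": calls.percentile_value,
            "all_fst_one": sorted(calls.all_fst_one),
            "missense_gene_counts": {
                p: {
                    "present": len(mis[p].genes_with_missense),
                    "exclusive": len(mis[p].genes_exclusive),
                    "fixed": len(mis[p].genes_with_fixed_missense),
                }
                for p in pops
            },
        }
    elif "genes_bed" not in config or not config.get("genes_bed"):
        summary["skipped"].append("selection: no gene intervals provided")

    # -- comparisons -----------------------------------------------------
    comps: list[GroupComparison] = []
    modern = div[div["era"] == "modern"]
    for stat in ("theta", "froh_100kb", "froh_2mb"):
        comps += pairwise_t_tests(modern[stat], modern["population"], stat)
    if loads is not None:
        lm = loads[loads["era"] == "modern"]
        comps += pairwise_t_tests(lm["relative_load"], lm["population"], "relative_load")
    if btab is not None:
        bm = btab[btab["era"] == "modern"]
        comps += pairwise_t_tests(bm["n_lof"], bm["population"], "n_lof")
    # temporal contrasts within populations sampled in both eras
    for pop in div["population"].unique():
        sub = div[div["population"] == pop]
        if set(sub["era"]) >= {"modern", "historical"}:
            for stat in ("theta", "froh_100kb", "froh_2mb"):
                for c in pairwise_t_tests(sub[stat], sub["era"], f"{pop}:{stat}"):
                    comps.append(c)
    ctab = comparisons_to_frame(comps)
    if len(ctab):
        ctab.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False, float_format="%.6g")
    summary["stages"]["comparisons"] = {"n_tests": int(len(ctab))}

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_json_ready(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary["out_dir"] = str(out_dir)
    return summary
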