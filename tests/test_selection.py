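"""Hudson F_ST, PBS construction, infinite-value capping and outlier calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from genoerode import cap_and_call, default_config, missense_summary, pairwise_fst, pbs, pbs_scan, simulate_dataset

from _util import make_dataset


def _two_pop_single_snp(ac1, n1, ac2, n2):
    """Dataset with one SNP and exact allele counts per population (diploids)."""
    def dosages(ac, n):
        d = []
        remaining = ac
        for _ in range(n):
            take = min(2, remaining)
            d.append(take)
            remaining -= take
        assert remaining == 0
        return d

    gt = np.array([dosages(ac1, n1) + dosages(ac2, n2)], dtype=np.int8)
    return make_dataset(gt, populations=["A"] * n1 + ["B"] * n2)


class TestHudsonFst:
    def test_identical_frequencies_clamp_to_zero(self):
        data = _two_pop_single_snp(10, 10, 10, 10)
        assert pairwise_fst(data, np.array([0]), "A", "B") == 0.0

    def test_alternate_fixation_gives_one(self):
        data = _two_pop_single_snp(20, 10, 0, 10)
        assert pairwise_fst(data, np.array([0]), "A", "B") == 1.0

    def test_closed_form_hand_evaluation(self):
        # p1 = 0.8, p2 = 0.2, 10 diploids each
        data = _two_pop_single_snp(16, 10, 4, 10)
        p1, p2 = 0.8, 0.2
        expected = (
            (p1 - p2) ** 2 - p1 * (1 - p1) / 19 - p2 * (1 - p2) / 19
        ) / (p1 * (1 - p2) + p2 * (1 - p1))
        got = pairwise_fst(data, np.array([0]), "A", "B")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_gene_flagged_no_data(self):
        data = _two_pop_single_snp(0, 5, 0, 5)
        assert np.isnan(pairwise_fst(data, np.array([0]), "A", "B"))


class TestPbs:
    def test_zero_divergence(self):
        assert pbs(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_hand_evaluated_branch_lengths(self):
        pbs_a, pbs_b, pbs_c = pbs(0.5, 0.5, 0.1)
        t = -np.log(0.5)
        t_bc = -np.log(0.9)
        assert pbs_a == pytest.approx((t + t - t_bc) / 2, abs=1e-12)
        assert pbs_a == pytest.approx(0.6404, abs=1e-4)
        assert pbs_b == pytest.approx(t_bc / 2, abs=1e-12)

    def test_fst_one_propagates_infinity(self):
        pbs_a, pbs_b, pbs_c = pbs(1.0, 0.2, 0.2)
        assert np.isposinf(pbs_a) and np.isposinf(pbs_b)
        assert np.isneginf(pbs_c)  # the opposite branch collapses

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pbs(1.2, 0.1, 0.1)
        with pytest.raises(ValueError):
            pbs(-0.1, 0.1, 0.1)

    @given(
        st.floats(0, 0.99), st.floats(0, 0.99), st.floats(0, 0.99)
    )
    def test_sum_identity(self, fab, fac, fbc):
        vals = pbs(fab, fac, fbc)
        t_sum = sum(-np.log1p(-f) for f in (fab, fac, fbc))
        assert sum(vals) == pytest.approx(t_sum / 2, rel=1e-9, abs=1e-12)

    @given(st.floats(0, 0.99), st.floats(0, 0.99), st.floats(0, 0.99))
    def test_invariant_to_relabeling_non_focal(self, fab, fac, fbc):
        # swapping B and C: AB<->AC, BC unchanged
        assert pbs(fab, fac, fbc)[0] == pytest.approx(pbs(fac, fab, fbc)[0], abs=1e-12)


class TestCapAndCall:
    def _scan(self, pbs_a, fst=0.5):
        n = len(pbs_a)
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "n_snps": 10,
                "fst_ab": fst,
                "fst_ac": fst,
                "fst_bc": fst,
                "pbs_A": pbs_a,
                "pbs_B": 0.1,
                "pbs_C": 0.1,
                "no_data": False,
            }
        )

    def test_infinities_replaced_by_finite_maximum(self):
        calls = cap_and_call(self._scan([0.1, 0.2, np.inf]), ["A", "B", "C"])
        assert calls.capped["pbs_A"].tolist() == [0.1, 0.2, 0.2]
        assert calls.n_infinite_replaced["A"] == 1

    def test_no_outliers_below_threshold(self):
        calls = cap_and_call(self._scan([0.5, 1.0, 2.9]), ["A", "B", "C"])
        assert calls.outliers == {"A": [], "B": [], "C": []}

    def test_outlier_and_uniqueness(self):
        calls = cap_and_call(self._scan([0.5, 3.5, np.inf]), ["A", "B", "C"])
        assert calls.outliers["A"] == ["g1", "g2"]  # inf capped to 3.5 > 3
        assert calls.unique_outliers["A"] == ["g1", "g2"]

    def test_capping_preserves_finite_rank_order(self):
        vals = [2.0, 0.3, np.inf, 1.1, 0.7]
        calls = cap_and_call(self._scan(vals), ["A", "B", "C"])
        capped = calls.capped["pbs_A"].to_numpy()
        finite = np.isfinite(vals)
        assert (
            np.argsort(capped[finite]).tolist()
            == np.argsort(np.asarray(vals)[finite]).tolist()
        )

    def test_all_fst_one_genes_reported(self):
        scan = self._scan([np.inf, 0.4], fst=1.0)
        scan.loc[1, ["fst_ab", "fst_ac", "fst_bc"]] = 0.3
        calls = cap_and_call(scan, ["A", "B", "C"])
        assert calls.all_fst_one == ["g0"]

    def test_all_infinite_raises(self):
        with pytest.raises(ValueError):
            cap_and_call(self._scan([np.inf, np.inf]), ["A", "B", "C"])


class TestMissenseSummary:
    def _data(self):
        # 3 missense sites in genes g1..g3 over pops A, B, C (2 diploids each)
        gt = np.array(
            [
                [2, 2, 0, 0, 0, 0],  # fixed in A only
                [1, 0, 1, 0, 0, 0],  # segregating in A and B
                [2, 2, 2, 2, 2, 2],  # fixed everywhere
            ],
            dtype=np.int8,
        )
        return make_dataset(
            gt,
            effect=np.full(3, "missense", dtype=object),
            gene=np.array(["g1", "g2", "g3"], dtype=object),
            populations=["A", "A", "B", "B", "C", "C"],
        )

    def test_exclusive_and_fixed_classification(self):
        out = missense_summary(self._data(), ["A", "B", "C"])
        assert out["A"].genes_exclusive == ("g1",)
        assert out["A"].genes_with_fixed_missense == ("g1",)
        assert out["B"].genes_with_missense == ("g2",)
        assert out["B"].genes_exclusive == ()

    def test_fixed_in_all_excluded_by_default(self):
        out = missense_summary(self._data(), ["A", "B", "C"])
        for pop in "ABC":
            assert "g3" not in out[pop].genes_with_missense
        kept = missense_summary(self._data(), ["A", "B", "C"], exclude_fixed_in_all=False)
        assert "g3" in kept["A"].genes_with_missense


def test_pbs_scan_on_planted_divergence():
    """A gene drifted in one population stands out in that population's PBS."""
    cfg = default_config(
        seed=0,
        scaffolds=(("scaf01", 3_000_000),),
        populations=(("A", 8, 0), ("B", 8, 0), ("C", 8, 0)),
        divergence_fst={"A": 0.05, "B": 0.05, "C": 0.05},
        n_sites=2000,
        coding_fraction=1.0,
        n_genes=40,
        gene_length=50_000,
        indel_fraction=0.0,
        sweeps=(("A", "gene0020", 0.6),),
    )
    data, _, _ = simulate_dataset(cfg)
    genes = pd.DataFrame(
        {
            "chrom": "scaf01",
            "start": 1,
            "end": 3_000_000,
            "gene": ["all"],
        }
    )
    # per-gene scan using the real gene intervals reconstructed from site annotations
    gene_rows = []
    for g, grp in data.sites.groupby("gene"):
        if g:
            gene_rows.append((grp["chrom"].iloc[0], grp["pos"].min(), grp["pos"].max(), g))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene"])
    scan = pbs_scan(data, genes, ["A", "B", "C"])
    scan = scan[~scan["no_data"]]
    top = scan.sort_values("pbs_A", ascending=False).iloc[0]
    assert top["gene"] == "gene0020"


def test_symmetric_null_has_no_outliers():
    """Equal background drift in all three populations: no gene exceeds PBS 3."""
    for seed in range(10):
        cfg = default_config(
            seed=seed,
            scaffolds=(("scaf01", 2_000_000),),
            populations=(("A", 8, 0), ("B", 8, 0), ("C", 8, 0)),
            divergence_fst={"A": 0.05, "B": 0.05, "C": 0.05},
            n_sites=1500,
            coding_fraction=1.0,
            n_genes=30,
            gene_length=50_000,
            indel_fraction=0.0,
        )
        data, _, _ = simulate_dataset(cfg)
        gene_rows = [
            (grp["chrom"].iloc[0], grp["pos"].min(), grp["pos"].max(), g)
            for g, grp in data.sites.groupby("gene")
            if g
        ]
        genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene"])
        scan = pbs_scan(data, genes, ["A", "B", "C"])
        calls = cap_and_call(scan, ["A", "B", "C"])
        assert all(len(v) == 0 for v in calls.outliers.values()), f"seed {seed}"
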