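"""Generator contracts: determinism, planted truth, Balding-Nichols calibration."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from genoerode import default_config, simulate_dataset, plant_roh
from genoerode.selection import pairwise_fst
from genoerode.synthetic import ConfigError, SimulationConfig


def _tiny_config(seed=0, **kw):
    base = dict(
        scaffolds=(("scaf01", 2_000_000),),
        populations=(("A", 3, 0), ("B", 3, 0)),
        n_sites=1000,
        n_genes=10,
        gene_length=5_000,
        indel_fraction=0.02,
    )
    base.update(kw)
    return default_config(seed=seed, **base)


def test_seed_determinism_byte_identical_files(tmp_path):
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    _, _, p1 = simulate_dataset(_tiny_config(seed=5), d1)
    _, _, p2 = simulate_dataset(_tiny_config(seed=5), d2)
    for key in p1:
        assert filecmp.cmp(p1[key], p2[key], shallow=False), f"{key} differs between runs"
    _, _, p3 = simulate_dataset(_tiny_config(seed=6), tmp_path / "c")
    assert not filecmp.cmp(p1["vcf"], p3["vcf"], shallow=False)


def test_zero_inbreeding_means_no_tracts():
    _, truth, _ = simulate_dataset(_tiny_config())
    assert truth.tracts.empty
    assert (truth.true_f == 0).all()


def test_single_planted_tract_gives_exact_f():
    cfg = default_config(
        seed=1,
        scaffolds=(("scaf01", 10_000_000),),
        populations=(("A", 1, 0),),
        n_sites=2000,
        n_genes=5,
        inbreeding_f={"A": 0.3},
        roh_length_mix=((1.0, 3_000_000, 3_000_000),),
    )
    _, truth, _ = simulate_dataset(cfg)
    assert len(truth.tracts) == 1
    assert truth.true_f["A_mod1"] == pytest.approx(0.3)


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        SimulationConfig(n_sites=0)
    with pytest.raises(ConfigError):
        SimulationConfig(scaffolds=(("s", 1000),), n_sites=5000)
    with pytest.raises(ConfigError):
        SimulationConfig(gerp_mixture=(0.5, 0.2, 0.2))
    with pytest.raises(ConfigError):
        SimulationConfig(divergence_fst={"Sumatra": 1.0})
    with pytest.raises(ConfigError):
        SimulationConfig(
            scaffolds=(("s", 500_000),),
            n_sites=100,
            inbreeding_f={"Sumatra": 0.2},
            roh_length_mix=((1.0, 1_000_000, 2_000_000),),
        )


class TestPlantRoh:
    def _inputs(self, n=200, k=4, seed=0):
        rng = np.random.default_rng(seed)
        sites = pd.DataFrame(
            {"chrom": "s1", "pos": np.sort(rng.choice(1_000_000, n, replace=False)) + 1}
        )
        freq = np.full((n, k), 0.5)
        derived = rng.binomial(2, freq).astype(np.int8)
        return sites, derived, freq, {"s1": 1_000_000}, rng

    def test_empty_tracts_identity(self):
        sites, derived, freq, scaf, rng = self._inputs()
        out = plant_roh(derived, sites, {0: []}, freq, scaf, rng)
        assert np.array_equal(out, derived)

    def test_whole_genome_tract_removes_all_hets(self):
        sites, derived, freq, scaf, rng = self._inputs()
        out = plant_roh(derived, sites, {1: [("s1", 1, 1_000_000)]}, freq, scaf, rng)
        assert not (out[:, 1] == 1).any()
        assert np.array_equal(out[:, 0], derived[:, 0])  # other samples untouched

    def test_het_count_drops_by_hets_inside_tract(self):
        sites, derived, freq, scaf, rng = self._inputs()
        tract = ("s1", 200_000, 600_000)
        inside = (sites["pos"] >= tract[1]) & (sites["pos"] <= tract[2])
        hets_before = (derived[:, 2] == 1).sum()
        hets_inside = (derived[inside.to_numpy(), 2] == 1).sum()
        out = plant_roh(derived, sites, {2: [tract]}, freq, scaf, rng)
        assert (out[:, 2] == 1).sum() == hets_before - hets_inside

    def test_overlapping_tracts_rejected(self):
        sites, derived, freq, scaf, rng = self._inputs()
        with pytest.raises(ConfigError, match="overlap"):
            plant_roh(
                derived, sites,
                {0: [("s1", 100, 5000), ("s1", 4000, 9000)]},
                freq, scaf, rng,
            )

    def test_out_of_bounds_tract_rejected(self):
        sites, derived, freq, scaf, rng = self._inputs()
        with pytest.raises(ConfigError, match="bounds"):
            plant_roh(derived, sites, {0: [("s1", 1, 2_000_000)]}, freq, scaf, rng)


def test_balding_nichols_fst_calibration():
    """Hudson F_ST between two populations with drift 0.2 recovers ~0.2.

    Monte-Carlo check of the Balding-Nichols expectation over 10 replicate
    seeds: with independent Beta drift of scale F per population around a
    shared ancestral frequency, the ratio-of-averages Hudson estimator over
    many sites converges to F.
    """
    for seed in range(10):
        cfg = default_config(
            seed=seed,
            scaffolds=(("scaf01", 10_000_000), ("scaf02", 10_000_000)),
            populations=(("A", 50, 0), ("B", 50, 0)),
            divergence_fst={"A": 0.2, "B": 0.2},
            n_sites=50_000,
            coding_fraction=0.0,
            n_genes=0,
            indel_fraction=0.0,
            missing_rate=0.0,
        )
        data, _, _ = simulate_dataset(cfg)
        fst = pairwise_fst(data, np.arange(data.n_sites), "A", "B")
        assert abs(fst - 0.2) < 0.03, f"seed {seed}: F_ST {fst:.4f}"


def test_sample_frequencies_recover_truth():
    """Sample allele frequencies converge to the generator's truth.

    At 1000 haplotypes per population the binomial standard error is < 0.016
    even at frequency 0.5, so nearly every site lands within 0.05 of truth.
    """
    cfg = default_config(
        seed=3,
        scaffolds=(("scaf01", 5_000_000),),
        populations=(("A", 500, 0),),
        divergence_fst={"A": 0.2},
        n_sites=2000,
        coding_fraction=0.0,
        n_genes=0,
        indel_fraction=0.0,
        aa_flip_fraction=0.1,
    )
    data, truth, _ = simulate_dataset(cfg)
    af = data.derived_allele_freq(data.population_mask("A"))
    err = np.abs(af - truth.pop_freqs["A"].to_numpy())
    assert np.mean(err < 0.05) >= 0.99


def test_missing_rate_and_annotation_structure(small_sim):
    cfg, data, truth = small_sim
    sites = data.sites
    # effect categories only inside genes; indels unannotated
    assert (sites.loc[sites["effect"] != "none", "gene"] != "").all()
    assert (sites.loc[sites["is_indel"], "effect"] == "none").all()
    assert sites.loc[sites["is_indel"], "gerp"].isna().all()
    # GERP mixture components land in their defining ranges
    labels = truth.site_labels
    g = sites["gerp"].to_numpy()
    assert (g[(labels == "constrained").to_numpy()] > 4).all()
    assert (g[(labels == "neutral").to_numpy()] < 1).all()
    # ancestral allele is always one of REF/ALT
    assert ((sites["aa"] == sites["ref"]) | (sites["aa"] == sites["alt"])).all()


def test_vcf_roundtrip_preserves_dataset(tmp_path):
    cfg = _tiny_config(seed=2, missing_rate=0.05)
    data, _, paths = simulate_dataset(cfg, tmp_path)
    from genoerode import read_vcf

    back = read_vcf(paths["vcf"], paths["samples"])
    assert np.array_equal(back.genotypes, data.genotypes)
    assert back.sites["pos"].equals(data.sites["pos"])
    assert back.sites["aa"].equals(data.sites["aa"])
    assert back.sites["effect"].equals(data.sites["effect"])
    assert back.sites["gene"].equals(data.sites["gene"])
    assert back.sites["is_indel"].equals(data.sites["is_indel"])
    assert np.allclose(back.sites["gerp"], data.sites["gerp"], atol=5e-4, equal_nan=True)
    assert back.depth is not None and np.array_equal(back.depth, data.depth)
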