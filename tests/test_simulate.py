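import numpy as np
import pandas as pd
import pytest

import heteroseq as h
from heteroseq import simulate


class TestAnnotation:
    def test_fixed_seed_is_byte_identical(self, small_config):
        a = h.simulate_annotation(small_config).to_csv()
        b = h.simulate_annotation(small_config).to_csv()
        assert a == b

    def test_construction_invariants(self):
        cfg = h.SimConfig(n_genes=100, n_chromosomes=2, chrom_length=2_000_000, seed=5)
        cat = h.simulate_annotation(cfg)
        assert len(cat) == 100
        assert (cat["end"] >= cat["start"]).all()
        assert (cat["length"] >= 200).all()
        for _, chrom in cat.groupby("chrom"):
            s = chrom.sort_values("start")
            assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()

    def test_sizing_error_when_over_capacity(self):
        cfg = h.SimConfig(n_genes=1000, n_chromosomes=1, chrom_length=10_000, seed=0)
        with pytest.raises(simulate.SizingError):
            h.simulate_annotation(cfg)


class TestTrioCounts:
    def test_fixed_seed_identical_matrix(self, small_config, small_catalog):
        c1, _, _ = h.simulate_trio_counts(small_catalog, small_config)
        c2, _, _ = h.simulate_trio_counts(small_catalog, small_config)
        assert c1.equals(c2)

    def test_exact_class_allocation(self):
        cfg = h.SimConfig(
            n_genes=1000, tissues=("0-L",), hybrids=("H1xH8",),
            class_fractions={"null": 0.8, "nonadd_up": 0.2}, seed=1,
        )
        cat = h.simulate_annotation(cfg)
        _, _, truth = h.simulate_trio_counts(cat, cfg)
        assert (truth["class"] == "nonadd_up").sum() == 200  # exact, not sampled

    def test_planted_mean_structure(self, small_experiment):
        _, _, truth = small_experiment
        add = truth[truth["class"] == "additive"]
        np.testing.assert_allclose(add["mu_f1"], (add["mu_p1"] + add["mu_p2"]) / 2)
        up = truth[truth["class"] == "nonadd_up"]
        np.testing.assert_allclose(
            up["mu_f1"], (up["mu_p1"] + up["mu_p2"]) / 2 * 4
        )  # effect_log2fc = 2
        pd_ = truth[truth["class"] == "parent_diff"]
        np.testing.assert_allclose(pd_["mu_p1"] / pd_["mu_p2"], 4.0)
        fu = truth[truth["class"] == "f1_unique"]
        assert set(np.round(np.abs(fu["log2_f1_mpv"]), 9)) == {2.0}

    def test_nb_moments(self):
        # empirical mean/variance of the generator match var = mu + alpha mu^2
        cfg = h.SimConfig(
            n_genes=1, tissues=("0-L",), hybrids=("H",), n_replicates=2,
            nb_dispersion=0.1, libsize_range=(1.0, 1.0), seed=3,
        )
        rng = np.random.default_rng(3)
        mu, alpha, n = 200.0, 0.1, 10_000
        r = 1 / alpha
        draws = rng.negative_binomial(r, r / (r + mu), n)
        assert draws.mean() == pytest.approx(mu, rel=0.05)
        assert draws.var() == pytest.approx(mu + alpha * mu**2, rel=0.05)

    def test_null_effect_degenerates(self):
        cfg = h.SimConfig(
            n_genes=300, tissues=("0-L",), hybrids=("H1xH8",),
            effect_log2fc=0.0, seed=7,
        )
        cat = h.simulate_annotation(cfg)
        counts, sheet, truth = h.simulate_trio_counts(cat, cfg)
        assert (truth["log2_f1_mpv"].abs() < 1e-12).all()
        _, _, sp = h.classify_trio(counts, sheet)
        # no planted signal: DE calls occur at roughly the false-positive rate
        assert sum(len(s) for s in sp.values()) <= 0.02 * len(cat)

    def test_zero_replicates_rejected(self):
        with pytest.raises(simulate.DesignError):
            h.SimConfig(n_replicates=0)


class TestTraits:
    EFFECTS = {"grain_yield": {"p1_mean": 5.0, "p2_mean": 11.0, "hph_pct": 50.0, "cv": 0.0}}

    def test_zero_noise_recovers_planted_hph_exactly(self):
        tab = h.simulate_traits(["AxB"], self.EFFECTS, n_plants=5, seed=0)
        het = h.heterosis_table(tab)
        assert het["hph_pct"].iloc[0] == pytest.approx(50.0, abs=1e-12)

    def test_zero_planted_mph_converges(self):
        effects = {"t": {"p1_mean": 10.0, "p2_mean": 20.0, "mph_pct": 0.0, "cv": 0.05}}
        tab = h.simulate_traits(["AxB"], effects, n_plants=4000, seed=1)
        het = h.heterosis_table(tab)
        assert abs(het["mph_pct"].iloc[0]) < 1.0

    def test_seeded_identity(self):
        t1 = h.simulate_traits(["AxB"], self.EFFECTS, seed=9)
        t2 = h.simulate_traits(["AxB"], self.EFFECTS, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            h.simulate_traits(
                ["AxB"], {"t": {"p1_mean": -1.0, "p2_mean": 2.0, "mph_pct": 0.0}}
            )


class TestQTLCatalog:
    def test_whole_chromosome_covers_all_genes(self, small_catalog):
        from heteroseq import qtl

        chrom = small_catalog["chrom"].iloc[0]
        qtls = pd.DataFrame(
            [("Q1", "GRNB", chrom, 1, 5_000_000)],
            columns=["qtl_id", "trait", "chrom", "start", "end"],
        )
        hits = qtl.map_genes(small_catalog, qtl.build_index(qtls))
        assert hits["n_genes"].iloc[0] == (small_catalog["chrom"] == chrom).sum()

    def test_planted_membership_exact(self, small_catalog):
        from heteroseq import qtl

        qtls, members = h.simulate_qtl_catalog(small_catalog, n_qtl=30, seed=4)
        hits = qtl.map_genes(small_catalog, qtl.build_index(qtls))
        mapped = {
            row.qtl_id: set(row.genes.split(";")) for row in hits.itertuples()
        }
        for qid, grp in members.groupby("qtl_id"):
            assert mapped[qid] == set(grp["gene_id"])

    def test_seeded_identity(self, small_catalog):
        a = h.simulate_qtl_catalog(small_catalog, 10, seed=2)[0]
        b = h.simulate_qtl_catalog(small_catalog, 10, seed=2)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_empty_catalog_rejected(self):
        empty = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand", "length"])
        with pytest.raises(ValueError):
            h.simulate_qtl_catalog(empty, 5)


class TestQPCRSim:
    def test_planted_ratio_four_gives_minus_two_cycles(self, small_experiment):
        _, _, truth = small_experiment
        up = truth[(truth["class"] == "nonadd_up") & (truth["tissue"] == "0-L")]
        gene = up["gene_id"].iloc[0]
        ct = h.simulate_qpcr(truth, "H1xH8", "0-L", genes=[gene], noise_sd=0.0, seed=0)
        dct = ct.groupby("sample_id").apply(
            lambda g: g["ct_target"].mean() - g["ct_reference"].mean(),
            include_groups=False,
        )
        # F1/P1 ratio 4 -> dCt difference of -2 cycles vs the P1 calibrator
        assert dct["F1"] - dct["P1"] == pytest.approx(-2.0, abs=1e-9)

    def test_seeded_identity(self, small_experiment):
        _, _, truth = small_experiment
        a = h.simulate_qpcr(truth, "H1xH8", "0-L", noise_sd=0.1, seed=5)
        b = h.simulate_qpcr(truth, "H1xH8", "0-L", noise_sd=0.1, seed=5)
        pd.testing.assert_frame_equal(a, b)


def test_config_invariants():
    with pytest.raises(ValueError, match="sum"):
        h.SimConfig(class_fractions={"null": 0.9})
    with pytest.raises(ValueError):
        h.SimConfig(nb_dispersion=-0.1)


def test_largest_remainder_is_exact():
    counts = simulate.largest_remainder_counts({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, 100)
    assert sum(counts.values()) == 100
    assert sorted(counts.values()) == [33, 33, 34]
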