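import numpy as np
import pandas as pd
import pytest

import heteroseq as h
from heteroseq import trio
from heteroseq.tables import deg_cells, ndeg_cells


class TestBuildSets:
    def test_sets_stored_verbatim(self):
        b = h.build_trio_sets(
            {"P1_vs_P2": ["a", "b"], "F1_vs_P1": ["b", "c"], "F1_vs_P2": ["c"]},
            "H", "0-L",
        )
        assert (b.deg2p, b.degp1, b.degp2) == ({"a", "b"}, {"b", "c"}, {"c"})

    def test_empty_calls_empty_sets(self):
        b = h.build_trio_sets(
            {"P1_vs_P2": [], "F1_vs_P1": [], "F1_vs_P2": []}, "H", "0-L"
        )
        assert b.deg2p == b.degp1 == b.degp2 == set()

    def test_missing_contrast_named(self):
        with pytest.raises(KeyError, match="F1_vs_P2"):
            h.build_trio_sets({"P1_vs_P2": [], "F1_vs_P1": []}, "H", "0-L")

    def test_duplicates_warn_and_dedupe(self):
        with pytest.warns(RuntimeWarning, match="duplicate"):
            b = h.build_trio_sets(
                {"P1_vs_P2": ["a", "a"], "F1_vs_P1": [], "F1_vs_P2": []}, "H", "0-L"
            )
        assert b.deg2p == {"a"}


class TestDeriveDEGFu:
    def _bundle(self):
        return trio.DEGSetBundle(
            "H", "0-L", deg2p={"c"}, degp1={"a", "b"}, degp2={"b", "c"}
        )

    def test_both_parents_rule(self):
        assert h.derive_degfu(self._bundle(), "both_parents") == {"b"}

    def test_either_parent_rule(self):
        assert h.derive_degfu(self._bundle(), "either_parent") == {"a", "b"}

    def test_parents_dominate_gives_empty(self):
        b = trio.DEGSetBundle("H", "0-L", deg2p={"a", "b", "c"},
                              degp1={"a", "b"}, degp2={"b", "c"})
        assert h.derive_degfu(b, "both_parents") == set()

    def test_degfu_disjoint_from_deg2p_always(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            b = trio.DEGSetBundle(
                "H", "t",
                deg2p=set(rng.choice(genes, 15)),
                degp1=set(rng.choice(genes, 15)),
                degp2=set(rng.choice(genes, 15)),
            )
            assert not (h.derive_degfu(b, "both_parents") & b.deg2p)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            h.derive_degfu(self._bundle(), "whatever")


class TestDeriveDEGFuSp:
    def test_exactly_one_tissue_rule(self):
        sp = h.derive_degfu_sp({"0-L": {"a", "b"}, "5-L": {"b", "c"}})
        assert sp == {"0-L": {"a"}, "5-L": {"c"}}  # b shared -> dropped from both

    def test_single_tissue_identity(self):
        assert h.derive_degfu_sp({"0-L": {"a", "b"}}) == {"0-L": {"a", "b"}}

    def test_shared_allowed_switch(self):
        sp = h.derive_degfu_sp({"0-L": {"a", "b"}, "5-L": {"b"}}, tissue_specific=False)
        assert sp == {"0-L": {"a", "b"}, "5-L": {"b"}}

    def test_sets_pairwise_disjoint(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        fu = {t: set(rng.choice(genes, 15)) for t in ("a", "b", "c", "d")}
        sp = h.derive_degfu_sp(fu)
        tissues = list(sp)
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                assert not (sp[tissues[i]] & sp[tissues[j]])


class TestAdditivity:
    def _experiment(self, f1_factor, cv, seed=0):
        rng = np.random.default_rng(seed)
        n = 30
        mu = np.full(n, 400.0)
        cols, names = [], []
        for geno, m in (("P1", mu), ("P2", mu), ("F1", mu * f1_factor)):
            for rep in range(1, 4):
                cols.append(np.maximum(rng.normal(m, cv * m), 0).round())
                names.append(f"H_{geno}_0-L_r{rep}")
        counts = pd.DataFrame(
            np.column_stack(cols), index=[f"g{i}" for i in range(n)], columns=names
        ).astype(int)
        sheet = pd.DataFrame(
            {
                "sample_id": names,
                "hybrid": "H",
                "genotype": [s.split("_")[1] for s in names],
                "tissue": "0-L",
                "replicate": [int(s[-1]) for s in names],
            }
        )
        # unit size factors: every fixture gene carries the planted shift, so
        # data-driven normalization would absorb a global F1 effect
        sf = pd.Series(1.0, index=names)
        return counts, sheet, sf

    def test_exact_midparent_is_additive(self):
        counts, sheet, sf = self._experiment(f1_factor=1.0, cv=0.0)
        res = h.additivity_test(counts, sheet, set(counts.index), "H", "0-L", size_factors=sf)
        assert (res["class"] == "additive").all()

    def test_fourfold_f1_is_nonadditive_up(self):
        counts, sheet, sf = self._experiment(f1_factor=4.0, cv=0.05)
        res = h.additivity_test(counts, sheet, set(counts.index), "H", "0-L", size_factors=sf)
        assert (res["class"] == "nonadditive_up").mean() >= 0.9

    def test_quarter_f1_is_nonadditive_down(self):
        counts, sheet, sf = self._experiment(f1_factor=0.25, cv=0.05)
        res = h.additivity_test(counts, sheet, set(counts.index), "H", "0-L", size_factors=sf)
        assert (res["class"] == "nonadditive_down").mean() >= 0.9

    def test_all_zero_gene_flagged_uninformative(self):
        counts, sheet, sf = self._experiment(f1_factor=1.0, cv=0.0)
        counts.iloc[0, :] = 0
        res = h.additivity_test(counts, sheet, set(counts.index), "H", "0-L", size_factors=sf)
        row = res[res["gene_id"] == "g0"].iloc[0]
        assert row["class"] == "additive" and row["flag"] == "uninformative"

    def test_partition_covers_tested_set(self):
        counts, sheet, sf = self._experiment(f1_factor=4.0, cv=0.1)
        genes = set(counts.index)
        res = h.additivity_test(counts, sheet, genes, "H", "0-L", size_factors=sf)
        assert set(res["gene_id"]) == genes
        assert set(res["class"]) <= {"additive", "nonadditive_up", "nonadditive_down"}


class TestSummaries:
    def test_published_cells_reproduce_totals(self):
        s = h.summarize_cells(deg_cells(), ndeg_cells())
        assert s.totals["degfu_sp_total"] == 24045
        assert s.totals["degfu_sp_by_hybrid"] == {"H1xH8": 11850, "T485xH8": 12195}
        assert s.totals["ndeg_total"] == 1393
        assert s.totals["ndeg_up"] == 766
        assert s.totals["ndeg_down"] == 627

    def test_percent_row_rounds_half_up(self):
        s = h.summarize_cells(deg_cells(), ndeg_cells())
        pct = s.tissue_percent.set_index("tissue")["percent"]
        assert pct["0-L"] == 4.65
        assert pct["0-S"] == 4.39
        assert pct["0-Z"] == 6.78
        assert pct["5-L"] == 3.04

    def test_up_plus_down_equals_total_everywhere(self):
        s = h.summarize_cells(deg_cells(), ndeg_cells())
        assert (
            s.ndeg_counts["up"] + s.ndeg_counts["down"] == s.ndeg_counts["total"]
        ).all()

    def test_empty_summary_has_undefined_percent(self):
        bundles = [trio.DEGSetBundle("H", "0-L")]
        s = h.summarize(bundles, None)
        assert s.totals["ndeg_total"] == 0
        assert np.isnan(s.tissue_percent["percent"].iloc[0])

    def test_key_mismatch_rejected(self):
        t2 = deg_cells()
        t4 = ndeg_cells()
        t4 = t4[t4["hybrid"] == "H1xH8"]
        with pytest.raises(ValueError):
            h.summarize_cells(t2, t4)
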