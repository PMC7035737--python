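import numpy as np
import pandas as pd
import pytest

from heteroseq import qtl


def random_instance(n_qtl, n_genes, seed):
    rng = np.random.default_rng(seed)
    chroms = [f"chr{c:02d}" for c in range(1, 4)]
    starts = rng.integers(1, 900_000, n_qtl)
    qtls = pd.DataFrame(
        {
            "qtl_id": [f"Q{i}" for i in range(n_qtl)],
            "trait": rng.choice(["GRNB", "TGRWT"], n_qtl),
            "chrom": rng.choice(chroms, n_qtl),
            "start": starts,
            "end": starts + rng.integers(100, 50_000, n_qtl),
        }
    )
    gstarts = rng.integers(1, 940_000, n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": rng.choice(chroms, n_genes),
            "start": gstarts,
            "end": gstarts + rng.integers(200, 5000, n_genes),
            "strand": "+",
        }
    )
    genes["length"] = genes["end"] - genes["start"] + 1
    return qtls, genes


def brute_force_hits(qtls, genes, rule="any_overlap"):
    """All-pairs oracle for gene-to-QTL overlap on inclusive coordinates."""
    hits = {}
    for q in qtls.itertuples():
        for g in genes.itertuples():
            if g.chrom != q.chrom:
                continue
            if rule == "any_overlap":
                ok = g.start <= q.end and q.start <= g.end
            else:
                ok = q.start <= g.start and g.end <= q.end
            if ok:
                hits.setdefault(q.qtl_id, set()).add(g.gene_id)
    return hits


class TestIndex:
    def test_empty_catalogue_returns_nothing(self):
        idx = qtl.build_index(pd.DataFrame(columns=qtl.QTL_COLUMNS))
        assert idx.query("chr01", 1, 10**9) == []

    def test_exact_interval_query(self):
        qtls = pd.DataFrame(
            [("Q1", "GRNB", "chr01", 100, 200)], columns=qtl.QTL_COLUMNS
        )
        assert qtl.build_index(qtls).query("chr01", 100, 200) == [("Q1", "GRNB")]

    def test_duplicate_ids_rejected(self):
        qtls = pd.DataFrame(
            [("Q1", "GRNB", "chr01", 1, 10), ("Q1", "TGRWT", "chr02", 1, 10)],
            columns=qtl.QTL_COLUMNS,
        )
        with pytest.raises(ValueError, match="duplicate"):
            qtl.build_index(qtls)

    def test_chromosome_name_normalization(self):
        qtls = pd.DataFrame([("Q1", "GRNB", "Chr01", 100, 200)], columns=qtl.QTL_COLUMNS)
        idx = qtl.build_index(qtls)
        assert idx.query("chr1", 150, 160) == [("Q1", "GRNB")]
        assert idx.query("1", 150, 160) == [("Q1", "GRNB")]


class TestMapping:
    def test_boundary_convention_inclusive(self):
        qtls = pd.DataFrame([("Q1", "GRNB", "c", 200, 500)], columns=qtl.QTL_COLUMNS)
        idx = qtl.build_index(qtls)
        gene = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "c", "start": [100], "end": [200],
             "strand": "+", "length": [101]}
        )
        assert qtl.map_genes(gene, idx)["n_genes"].iloc[0] == 1  # 1-bp overlap
        qtls2 = pd.DataFrame([("Q1", "GRNB", "c", 201, 500)], columns=qtl.QTL_COLUMNS)
        assert len(qtl.map_genes(gene, qtl.build_index(qtls2))) == 0  # adjacent

    def test_containment_hit(self):
        qtls = pd.DataFrame([("Q1", "GRNB", "c", 50, 500)], columns=qtl.QTL_COLUMNS)
        gene = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "c", "start": [100], "end": [200],
             "strand": "+", "length": [101]}
        )
        assert qtl.map_genes(gene, qtl.build_index(qtls))["n_genes"].iloc[0] == 1

    @pytest.mark.parametrize("rule", ["any_overlap", "contained"])
    def test_matches_brute_force_oracle(self, rule):
        qtls, genes = random_instance(200, 500, seed=17)
        hits = qtl.map_genes(genes, qtl.build_index(qtls), overlap_rule=rule)
        oracle = brute_force_hits(qtls, genes, rule)
        got = {r.qtl_id: set(r.genes.split(";")) for r in hits.itertuples()}
        assert got == oracle

    def test_order_invariance(self):
        qtls, genes = random_instance(50, 200, seed=3)
        idx = qtl.build_index(qtls)
        a = qtl.map_genes(genes, idx)
        b = qtl.map_genes(genes.sample(frac=1, random_state=0), idx)
        pd.testing.assert_frame_equal(a, b)

    def test_enlarging_interval_never_loses_genes(self):
        qtls, genes = random_instance(30, 300, seed=5)
        base = qtl.map_genes(genes, qtl.build_index(qtls))
        grown = qtls.copy()
        grown["start"] = (grown["start"] - 10_000).clip(lower=1)
        grown["end"] = grown["end"] + 10_000
        bigger = qtl.map_genes(genes, qtl.build_index(grown))
        base_counts = dict(zip(base["qtl_id"], base["n_genes"]))
        big_counts = dict(zip(bigger["qtl_id"], bigger["n_genes"]))
        for qid, n in base_counts.items():
            assert big_counts.get(qid, 0) >= n

    def test_missing_chromosome_warns(self):
        qtls = pd.DataFrame([("Q1", "GRNB", "chr01", 1, 100)], columns=qtl.QTL_COLUMNS)
        gene = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr99", "start": [1], "end": [50],
             "strand": "+", "length": [50]}
        )
        with pytest.warns(RuntimeWarning, match="chr99"):
            hits = qtl.map_genes(gene, qtl.build_index(qtls))
        assert len(hits) == 0


class TestIntersect:
    def _hits(self, ids, trait="GRNB"):
        return pd.DataFrame(
            {"qtl_id": list(ids), "trait": trait, "n_genes": 1, "genes": "g", "source": "x"}
        )

    def test_single_experiment_identity(self):
        out = qtl.filter_and_intersect({"e1": self._hits(["Q1", "Q2"])})
        assert out["common_qtls"] == ["Q1", "Q2"]

    def test_disjoint_experiments_empty(self):
        out = qtl.filter_and_intersect(
            {"e1": self._hits(["Q1"]), "e2": self._hits(["Q2"])}
        )
        assert out["common_qtls"] == []

    def test_planted_intersection_recovered(self):
        out = qtl.filter_and_intersect(
            {"e1": self._hits(["Q1", "Q2", "Q3"]), "e2": self._hits(["Q2", "Q3", "Q4"])}
        )
        assert out["common_qtls"] == ["Q2", "Q3"]

    def test_trait_filter_applies(self):
        mixed = pd.concat([self._hits(["Q1"], "GRNB"), self._hits(["Q2"], "other")])
        out = qtl.filter_and_intersect({"e1": mixed}, traits=("GRNB",))
        assert out["common_qtls"] == ["Q1"]

    def test_unknown_trait_rejected_with_list(self):
        with pytest.raises(ValueError, match="valid"):
            qtl.filter_and_intersect(
                {"e1": self._hits(["Q1"])}, traits=("BOGUS",), valid_traits={"GRNB"}
            )
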