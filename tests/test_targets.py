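"""CPM, differential test, BH adjustment and the filter cascade."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from sarcoscreen import simulate as sim
from sarcoscreen import targets as tg


def bh_oracle(pvals):
    """Textbook step-up: adj_i = min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum(1.0, p[order] * m / (np.arange(m) + 1))
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestCpm:
    def test_column_scaling(self):
        counts = pd.DataFrame({"s1": [10, 90, 900]}, index=["a", "b", "c"])
        cpm = tg.cpm_normalize(counts)
        assert list(cpm["s1"]) == [10_000, 90_000, 900_000]

    def test_uniform_counts(self):
        counts = pd.DataFrame(np.full((5, 2), 7), columns=["s1", "s2"])
        cpm = tg.cpm_normalize(counts)
        assert np.allclose(cpm.to_numpy(), 1e6 / 5)

    def test_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)) + 1)
        assert np.allclose(tg.cpm_normalize(counts).sum(axis=0), 1e6, atol=1e-6)

    def test_zero_sum_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="zero-sum"):
            tg.cpm_normalize(counts)


class TestBenjaminiHochberg:
    def test_stepup_example(self):
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_textbook_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(2, 40)))
            assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_oracle(p))

    def test_adjusted_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=100)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p)


class TestDifferentialExpression:
    def test_flat_gene_is_null(self):
        counts = pd.DataFrame(
            np.full((3, 6), 50), index=["g1", "g2", "g3"],
            columns=["T1", "T2", "T3", "N1", "N2", "N3"],
        )
        groups = {c: "tumor" if c.startswith("T") else "normal" for c in counts.columns}
        de = tg.differential_expression(counts, groups)
        assert np.allclose(de["log2fc"], 0.0)
        assert np.all(de["p_value"] > 0.9)

    def test_planted_fourfold_gene_detected(self):
        detected = 0
        n_runs = 25
        for seed in range(n_runs):
            counts, truth = sim.gen_expression_counts(
                200, 13, 13, de_fraction=0.05, lfc_magnitude=2.0,
                dispersion=0.05, seed=seed,
            )
            groups = {c: "tumor" if c.startswith("T") else "normal" for c in counts.columns}
            de = tg.differential_expression(counts, groups)
            up = set(truth.loc[truth["direction"] == 1, "gene"])
            hits, _ = tg.filter_tsg(de)
            detected += len(up & hits) / len(up)
        assert detected / n_runs >= 0.95

    def test_paired_mode_requires_matching(self):
        counts = pd.DataFrame(
            np.arange(24).reshape(4, 6), columns=["T1", "T2", "T3", "N1", "N2", "N3"]
        )
        groups = {c: "tumor" if c.startswith("T") else "normal" for c in counts.columns}
        with pytest.raises(ValueError, match="unmatched"):
            tg.differential_expression(
                counts, groups, paired=True, pairs=[("T1", "T2"), ("T3", "N1")]
            )

    def test_small_group_rejected(self):
        counts = pd.DataFrame(np.ones((3, 3)), columns=["T1", "T2", "N1"])
        groups = {"T1": "tumor", "T2": "tumor", "N1": "normal"}
        with pytest.raises(ValueError, match=">= 2"):
            tg.differential_expression(counts, groups)


def make_records(rows):
    df = pd.DataFrame(
        rows, columns=["gene", "log2fc", "p_value", "adj_p", "mean_cpm_tumor"]
    )
    return df.set_index("gene", drop=False)


class TestFilterCascade:
    def test_tsg_boundaries(self):
        recs = make_records(
            [
                ("inclusive_fc", 1.0, 0.01, 0.049, 100),   # |log2fc| = 1 exactly: in
                ("strict_alpha", 2.0, 0.02, 0.05, 100),    # adj_p = 0.05 exactly: out
                ("down", -1.5, 0.001, 0.01, 100),
                ("weak", 0.5, 0.001, 0.01, 100),
            ]
        )
        up, down = tg.filter_tsg(recs)
        assert up == {"inclusive_fc"}
        assert down == {"down"}

    def test_toy_table_bruteforce(self, rng):
        rows = []
        for i in range(6):
            rows.append((f"g{i}", rng.uniform(-3, 3), 0.001, rng.uniform(0, 0.2), 50))
        recs = make_records(rows)
        up, down = tg.filter_tsg(recs)
        expect_up = {
            r.gene for r in recs.itertuples() if r.log2fc >= 1 and r.adj_p < 0.05
        }
        expect_down = {
            r.gene for r in recs.itertuples() if r.log2fc <= -1 and r.adj_p < 0.05
        }
        assert (up, down) == (expect_up, expect_down)

    def test_pan_cancer_exclusion(self):
        tsgs = {f"g{i}" for i in range(10)}
        rows = []
        for i in range(8):  # g8, g9 uncovered
            for cancer in ("BRCA", "LUAD"):
                rows.append((f"g{i}", cancer, i < 4 and cancer == "BRCA"))
        pan = pd.DataFrame(rows, columns=["gene", "cancer", "up"])
        res = tg.pan_cancer_exclude(tsgs, pan)
        assert res.specific == {"g4", "g5", "g6", "g7"}
        assert res.unevaluated == {"g8", "g9"}
        assert res.retained == res.specific | res.unevaluated

    def test_functional_classes_and_multimembership(self):
        annot = pd.DataFrame(
            [("g1", "kinase"), ("g1", "transcription_factor"), ("g2", "metabolism"),
             ("g3", "kinase")],
            columns=["gene", "class"],
        )
        sets = tg.classify_functional_sets({"g1", "g2"}, annot)
        assert sets["kinase"] == {"g1"}
        assert sets["transcription_factor"] == {"g1"}
        assert sets["metabolism"] == {"g2"}
        assert sets["cell_surface"] == set()

    def test_empty_annotation_gives_zero_counts(self):
        sets = tg.classify_functional_sets(
            {"g1"}, pd.DataFrame(columns=["gene", "class"])
        )
        assert all(len(s) == 0 for s in sets.values())

    def test_drug_target_overlap_union_semantics(self):
        class_sets = {"kinase": {"A", "B", "C"}}
        overlap = tg.drug_target_overlap(
            class_sets, {"X": ["B"], "Y": ["B", "D"]}
        )
        assert overlap["kinase"]["targeted"] == {"B"}
        assert overlap["kinase"]["untargeted"] == {"A", "C"}
        assert overlap["gene_drugs"]["B"] == ["X", "Y"]

    def test_no_drugs_all_untargeted(self):
        overlap = tg.drug_target_overlap({"kinase": {"A"}}, {})
        assert overlap["kinase"]["untargeted"] == {"A"}

    def test_act_surface_boundaries(self):
        recs = make_records(
            [
                ("exact", 2.0, 0.001, 0.001, 90.0),    # both boundaries inclusive
                ("low_fc", 1.9, 0.001, 0.001, 500.0),
                ("low_cpm", 3.0, 0.001, 0.001, 89.9),
            ]
        )
        passing, skipped = tg.act_surface_filter(
            {"exact", "low_fc", "low_cpm"}, recs
        )
        assert passing == {"exact"}
        assert skipped == 0

    def test_act_surface_restricted_to_surface_genes_and_skips_missing(self):
        recs = make_records([("a", 3.0, 0.001, 0.001, 200.0)])
        passing, skipped = tg.act_surface_filter(
            {"a", "b"}, recs, surface_genes={"a", "b"}
        )
        assert passing == {"a"}
        assert skipped == 1  # b has no record

    def test_cascade_monotonicity(self, rng):
        counts, _ = sim.gen_expression_counts(300, 6, 6, de_fraction=0.2, seed=4)
        groups = {c: "tumor" if c.startswith("T") else "normal" for c in counts.columns}
        de = tg.differential_expression(counts, groups)
        tsgs, _ = tg.filter_tsg(de)
        pan = pd.DataFrame(
            {"gene": list(tsgs)[:5], "cancer": "BRCA", "up": True}
        )
        res = tg.pan_cancer_exclude(tsgs, pan)
        act, _ = tg.act_surface_filter(tsgs, de)
        assert res.retained <= tsgs
        assert act <= tsgs


class TestScrnaFilter:
    def make_matrix(self, pct_by_type, n_cells=100):
        # one gene expressed in the stated fraction of each cluster's cells
        cells, rows, clusters = [], [], {}
        for ctype, pct in pct_by_type.items():
            for i in range(n_cells):
                cell = f"{ctype}_c{i}"
                cells.append(cell)
                clusters[cell] = ctype
                rows.append([1 if i < pct * n_cells else 0])
        return pd.DataFrame(rows, index=cells, columns=["g1"]), clusters

    def test_26_percent_passes_not_broad(self):
        mat, cl = self.make_matrix({"osteoblast": 0.26, "tcell": 0.0})
        res = tg.scrna_percent_expressed_filter(mat, cl)
        assert res.loc["g1", "passes"] and not res.loc["g1", "broad"]

    def test_exactly_25_percent_fails(self):
        mat, cl = self.make_matrix({"osteoblast": 0.25})
        res = tg.scrna_percent_expressed_filter(mat, cl)
        assert not res.loc["g1", "passes"]

    def test_five_cell_types_is_broad(self):
        mat, cl = self.make_matrix({f"type{i}": 0.5 for i in range(5)})
        res = tg.scrna_percent_expressed_filter(mat, cl)
        assert res.loc["g1", "broad"]

    def test_unclustered_cell_rejected(self):
        mat, cl = self.make_matrix({"a": 0.5})
        cl.pop(mat.index[0])
        with pytest.raises(ValueError, match="unclustered"):
            tg.scrna_percent_expressed_filter(mat, pd.Series(cl))


class TestOverlaps:
    def test_nact_overlap_subsets_of_tsgs(self):
        recs = make_records(
            [("up1", 2.0, 0.001, 0.001, 10), ("dn1", -2.0, 0.001, 0.001, 10),
             ("up2", 2.0, 0.001, 0.001, 10)]
        )
        up, down = tg.nact_overlap(recs, tsgs={"up1", "dn1", "other"})
        assert up == {"up1"} and down == {"dn1"}

    def test_nact_disjoint_gives_empty(self):
        recs = make_records([("x", 3.0, 0.001, 0.001, 10)])
        assert tg.nact_overlap(recs, tsgs={"y"}) == (set(), set())

    def test_multiomic_intersections(self):
        both_up, both_down = tg.multiomic_intersect(
            {"a", "b"}, {"c"}, {"b", "z"}, {"c", "d"}
        )
        assert both_up == {"b"} and both_down == {"c"}
        assert tg.multiomic_intersect({"a"}, {"b"}, {"x"}, {"y"}) == (set(), set())
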