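"""Signature scoring and TCR repertoire statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from fluxshift.readouts import (
    GeneSignature,
    auc_signature_score,
    derive_signature,
    preprocess_repertoire,
    pseudobulk_mean,
    repertoire_metrics,
    ssgsea_score,
)


def _de(n, n_pass):
    genes = [f"g{i:03d}" for i in range(n)]
    fdr = np.linspace(0.001, 0.04, n)
    fdr[n_pass:] = 0.5
    return pd.DataFrame({"log2_fc": np.ones(n), "fdr": fdr}, index=genes)


class TestSignature:
    def test_top_63_of_70_passing(self):
        sig = derive_signature(_de(100, 70))
        assert len(sig) == 63

    def test_fewer_survivors_warn(self):
        with pytest.warns(UserWarning, match="40"):
            sig = derive_signature(_de(100, 40))
        assert len(sig) == 40

    def test_fdr_ties_broken_by_larger_fold_change(self):
        de = pd.DataFrame(
            {"log2_fc": [1.0, 3.0, 2.0], "fdr": [0.01, 0.01, 0.01]},
            index=["a", "b", "c"],
        )
        sig = derive_signature(de, top_k=2)
        assert sig.genes == ("b", "c")

    def test_missing_fdr_column_rejected(self):
        with pytest.raises(ValueError, match="fdr"):
            derive_signature(pd.DataFrame({"log2_fc": [1.0]}, index=["a"]))


def _rankings(order, n_cells=1):
    """Genes ranked in the given order (first = rank 1) for every cell."""
    ranks = pd.DataFrame(
        {f"c{j}": np.arange(1, len(order) + 1) for j in range(n_cells)}, index=order
    )
    return ranks


class TestAucScore:
    def test_all_set_genes_on_top_scores_one(self):
        sig = GeneSignature("s", ("a", "b"))
        ranks = _rankings(["a", "b"] + [f"x{i}" for i in range(98)])
        assert auc_signature_score(ranks, sig).iloc[0] == pytest.approx(1.0)

    def test_no_set_gene_in_top_fraction_scores_zero(self):
        sig = GeneSignature("s", ("a", "b"))
        ranks = _rankings([f"x{i}" for i in range(98)] + ["a", "b"])
        assert auc_signature_score(ranks, sig).iloc[0] == 0.0

    def test_missing_set_genes_never_recover(self):
        sig = GeneSignature("s", ("a", "missing1", "missing2"))
        ranks = _rankings(["a"] + [f"x{i}" for i in range(99)])
        partial = auc_signature_score(ranks, sig).iloc[0]
        full = auc_signature_score(ranks, GeneSignature("s", ("a",))).iloc[0]
        assert 0 < partial < full <= 1.0

    def test_invalid_top_frac_rejected(self):
        with pytest.raises(ValueError):
            auc_signature_score(_rankings(["a", "b"]), GeneSignature("s", ("a",)), top_frac=0.0)

    def test_random_rankings_match_permutation_oracle(self, rng):
        """Mean AUC over random rankings equals the permutation-null mean."""
        n_genes, k, n_cells = 200, 10, 400
        sig = GeneSignature("s", tuple(f"g{i}" for i in range(k)))
        genes = [f"g{i}" for i in range(n_genes)]
        cols = {}
        for j in range(n_cells):
            perm = rng.permutation(n_genes)
            cols[f"c{j}"] = np.empty(n_genes, dtype=int)
            cols[f"c{j}"][perm] = np.arange(1, n_genes + 1)
        ranks = pd.DataFrame(cols, index=genes)
        scores = auc_signature_score(ranks, sig)
        # independent oracle: direct expectation by simulating the null
        threshold = math.ceil(0.05 * n_genes)
        max_auc = sum(min(x, k) for x in range(1, threshold + 1))
        sims = []
        for _ in range(4000):
            r = np.sort(rng.choice(n_genes, size=k, replace=False) + 1)
            r = r[r <= threshold]
            sims.append(np.sum(threshold - r + 1) / max_auc)
        se = np.std(sims) / math.sqrt(n_cells)
        assert abs(scores.mean() - np.mean(sims)) < 3 * se + 1e-3

    def test_invariant_to_nonset_gene_relabelling(self):
        sig = GeneSignature("s", ("a",))
        base = ["x0", "a"] + [f"x{i}" for i in range(1, 99)]
        relabelled = ["y0", "a"] + [f"y{i}" for i in range(1, 99)]
        s1 = auc_signature_score(_rankings(base), sig).iloc[0]
        s2 = auc_signature_score(_rankings(relabelled), sig).iloc[0]
        assert s1 == s2


class TestSsgsea:
    def test_top_heavy_set_scores_positive_and_maximal(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = pd.Series(np.arange(10, 0, -1, dtype=float), index=genes)
        sig = GeneSignature("s", ("g0", "g1"))
        top = ssgsea_score(expr, sig).iloc[0]
        assert top > 0
        for _ in range(50):  # no permutation of the same values scores higher
            perm = pd.Series(expr.to_numpy(), index=rng.permutation(genes))
            assert ssgsea_score(perm, sig).iloc[0] <= top + 1e-12

    def test_matches_hand_coded_summation(self):
        genes = [f"g{i}" for i in range(10)]
        values = np.array([9.0, 3.0, 7.0, 1.0, 5.0, 8.0, 2.0, 6.0, 4.0, 0.5])
        expr = pd.Series(values, index=genes)
        sig = GeneSignature("s", ("g0", "g4"))
        alpha = 0.25
        order = np.argsort(-values)
        member = np.isin(order, [0, 4])
        w = (10 - np.arange(10.0)) ** alpha
        cdf_in = np.cumsum(np.where(member, w, 0)) / w[member].sum()
        cdf_out = np.cumsum(~member) / 8
        assert ssgsea_score(expr, sig).iloc[0] == pytest.approx(float(np.sum(cdf_in - cdf_out)))

    def test_alpha_zero_reduces_to_ecdf_difference(self):
        genes = ["a", "b", "c", "d"]
        expr = pd.Series([4.0, 3.0, 2.0, 1.0], index=genes)
        sig = GeneSignature("s", ("a", "c"))
        # positions: a(in), b(out), c(in), d(out)
        # cdf_in  = 1/2, 1/2, 1, 1 ; cdf_out = 0, 1/2, 1/2, 1
        expected = (0.5 - 0) + (0.5 - 0.5) + (1 - 0.5) + (1 - 1)
        assert ssgsea_score(expr, sig, alpha=0.0).iloc[0] == pytest.approx(expected)

    def test_empty_intersection_rejected(self):
        expr = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(expr, GeneSignature("s", ("zz",)))


class TestPseudobulk:
    def test_mean_within_patient(self):
        scores = pd.Series({"c1": 0.2, "c2": 0.4, "c3": 0.9})
        labels = {"c1": "p1", "c2": "p1", "c3": "p2"}
        out = pseudobulk_mean(scores, labels)
        assert out["p1"] == pytest.approx(0.3)
        assert out["p2"] == pytest.approx(0.9)

    def test_unlabelled_cell_rejected(self):
        with pytest.raises(ValueError, match="c2"):
            pseudobulk_mean(pd.Series({"c1": 0.1, "c2": 0.2}), {"c1": "p1"})

    def test_matches_grouped_mean_oracle(self, rng):
        cells = [f"c{i}" for i in range(60)]
        scores = pd.Series(rng.random(60), index=cells)
        labels = {c: f"p{i % 5}" for i, c in enumerate(cells)}
        out = pseudobulk_mean(scores, labels)
        frame = pd.DataFrame({"s": scores, "p": pd.Series(labels)})
        expected = frame.groupby("p")["s"].mean()
        pd.testing.assert_series_equal(out, expected, check_names=False)


class TestRepertoirePreprocessing:
    def test_nucleotide_variants_pool_to_one_protein(self):
        # two codon variants of the same peptide, counts 3 + 4 -> one clone of 7
        raw = pd.DataFrame({
            "nt_seq": ["ATGGCT", "ATGGCC"],  # both code MA
            "frame": ["in", "in"],
            "count": [3, 4],
        })
        table = preprocess_repertoire(raw)
        assert list(table.index) == ["MA"]
        assert table.loc["MA", "count"] == 7

    def test_out_of_frame_removed_regardless_of_count(self):
        raw = pd.DataFrame({
            "nt_seq": ["ATGGCT", "ATGGCTA"],
            "frame": ["in", "out"],
            "count": [5, 50],
        })
        table = preprocess_repertoire(raw)
        assert table["count"].sum() == 5

    def test_singletons_dropped_after_pooling(self):
        raw = pd.DataFrame({
            "nt_seq": ["ATGGCT", "TGGAAA"],
            "frame": ["in", "in"],
            "count": [2, 1],
        })
        table = preprocess_repertoire(raw)
        assert len(table) == 1 and table["count"].sum() == 2

    def test_count_conservation(self, rng):
        from fluxshift.synthetic import synthesize_repertoire

        raw = synthesize_repertoire(60, 1.2, 8000, seed=4)
        table = preprocess_repertoire(raw)
        in_frame = raw[raw["frame"] == "in"]
        aa = in_frame["nt_seq"].map(
            lambda s: str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(s).translate())
        )
        pooled = in_frame.assign(aa=aa).groupby("aa")["count"].sum()
        dropped = pooled[pooled < 2].sum()
        assert table["count"].sum() == in_frame["count"].sum() - dropped

    def test_non_dna_rejected(self):
        raw = pd.DataFrame({"nt_seq": ["ATGXYZ"], "frame": ["in"], "count": [5]})
        with pytest.raises(ValueError, match="non-DNA"):
            preprocess_repertoire(raw)


class TestRepertoireMetrics:
    def test_uniform_four_clone_closed_form(self):
        table = pd.DataFrame({"count": [5, 5, 5, 5]}, index=list("abcd"))
        m = repertoire_metrics(table)
        assert m.richness == 4
        assert m.shannon_entropy == pytest.approx(math.log(4))
        assert m.pielou_evenness == pytest.approx(1.0)
        assert m.clonality == pytest.approx(0.0)
        assert m.n_exp10 == 0 and m.n_exp100 == 0

    def test_dominant_clone_worked_example(self):
        # frequencies 0.97/0.01/0.01/0.01: median 0.01, 10x threshold 0.1
        table = pd.DataFrame({"count": [97, 1, 1, 1]}, index=list("abcd"))
        m = repertoire_metrics(table)
        assert m.n_exp10 == 1
        assert m.n_exp100 == 0

    def test_single_clone_degenerate_convention(self):
        m = repertoire_metrics(pd.DataFrame({"count": [7]}, index=["a"]))
        assert m.richness == 1
        assert m.shannon_entropy == 0.0
        assert m.pielou_evenness == 1.0 and m.clonality == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            repertoire_metrics(pd.DataFrame({"count": []}))

    def test_two_point_distribution_closed_form(self):
        table = pd.DataFrame({"count": [3, 1]}, index=["a", "b"])
        m = repertoire_metrics(table)
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert m.shannon_entropy == pytest.approx(h)
        assert m.pielou_evenness == pytest.approx(h / math.log(2))

    def test_feeding_dominant_clone_never_decreases_clonality(self, rng):
        for _ in range(100):
            counts = rng.integers(2, 100, size=int(rng.integers(2, 12)))
            table = pd.DataFrame({"count": counts},
                                 index=[f"c{i}" for i in range(len(counts))])
            before = repertoire_metrics(table).clonality
            counts2 = counts.copy()
            counts2[np.argmax(counts2)] += int(rng.integers(1, 50))
            table2 = pd.DataFrame({"count": counts2}, index=table.index)
            after = repertoire_metrics(table2).clonality
            assert after >= before - 1e-12

    def test_pielou_bounded_on_random_tables(self, rng):
        for _ in range(50):
            counts = rng.integers(2, 500, size=int(rng.integers(1, 20)))
            m = repertoire_metrics(pd.DataFrame({"count": counts}))
            assert 0.0 <= m.pielou_evenness <= 1.0 + 1e-12
            assert 0.0 <= m.clonality <= 1.0
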