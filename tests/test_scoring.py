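"""The five activity scores against brute-force oracles, plus panel algebra."""

import numpy as np
import pandas as pd
import pytest

import twascell as tc
from twascell.genesets import GeneSet
from conftest import adata_from_dense


# ---------------------------------------------------------------- oracles


def rank_order(values, gene_ids):
    """Descending-expression total order with gene-id tiebreak; 1-based ranks."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    ranks = {}
    for pos, i in enumerate(order, start=1):
        ranks[gene_ids[i]] = pos
    return ranks


def aucell_oracle(values, gene_ids, gene_set, top_fraction):
    import math

    ranks = rank_order(values, gene_ids)
    g = len(gene_ids)
    r_max = math.ceil(top_fraction * g)
    set_ranks = sorted(ranks[x] for x in gene_set)
    area = sum(sum(1 for r in set_ranks if r <= k) for k in range(1, r_max + 1))
    max_area = sum(min(k, len(set_ranks)) for k in range(1, r_max + 1))
    return area / max_area


def ucell_u_oracle(values, gene_ids, gene_set):
    """Mann-Whitney U of set-gene ranks vs complement by pairwise counting."""
    ranks = rank_order(values, gene_ids)
    u = 0
    for s in gene_set:
        for c in gene_ids:
            if c in gene_set:
                continue
            if ranks[s] > ranks[c]:
                u += 1
    return u


def ssgsea_oracle(values, gene_ids, gene_set, alpha):
    ranks = rank_order(values, gene_ids)
    g = len(gene_ids)
    n_s = len(gene_set)
    walk = sorted(gene_ids, key=lambda x: ranks[x])
    weights = {x: (g - ranks[x] + 1) ** alpha for x in gene_set}
    norm = sum(weights.values())
    rs, total = 0.0, 0.0
    for x in walk:
        rs += weights[x] / norm if x in gene_set else -1.0 / (g - n_s)
        total += rs
    return total


# ------------------------------------------------------------ module score


class TestModuleMean:
    def test_whole_transcriptome_set_scores_near_zero(self):
        rng = np.random.default_rng(0)
        adata = adata_from_dense(rng.exponential(1.0, size=(30, 40)))
        s = tc.score_module_mean(adata, GeneSet("all", tuple(adata.var_names)), seed=0)
        assert np.allclose(s, 0.0, atol=1e-12)  # controls fall back to the set itself

    def test_additive_shift_moves_score_linearly(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(1.0, size=(25, 30))
        genes = [f"g{i:03d}" for i in range(30)]
        gene_set = GeneSet("s", tuple(genes[:5]))
        base = tc.score_module_mean(adata_from_dense(x, genes), gene_set,
                                    n_bins=1, seed=3)
        shifted = x.copy()
        shifted[:, :5] += 0.7
        after = tc.score_module_mean(adata_from_dense(shifted, genes), gene_set,
                                     n_bins=1, seed=3)
        # one bin: the control pool is every non-set gene, identical draws
        assert np.allclose(after - base, 0.7)

    def test_planted_cells_score_higher(self, small_sim, lognorm_sim):
        from scipy import stats

        s = tc.score_module_mean(lognorm_sim, small_sim.truth_risk_genes, seed=11)
        active = small_sim.adata.obs["truth_active"].reindex(s.index).to_numpy()
        t = stats.ttest_ind(s[active], s[~active], alternative="greater")
        assert t.pvalue < 1e-6

    def test_empty_intersection_lists_missing(self):
        adata = adata_from_dense(np.ones((3, 4)) + np.eye(3, 4))
        with pytest.raises(ValueError, match="missing"):
            tc.score_module_mean(adata, GeneSet("s", ("nope1", "nope2")), seed=0)


# ----------------------------------------------------------------- aucell


class TestAucell:
    def test_set_at_top_is_maximal(self):
        x = np.array([[9.0, 8.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.4, 0.3, 0.2]])
        adata = adata_from_dense(x)
        s = tc.score_aucell(adata, GeneSet("s", ("g000", "g001")), top_fraction=0.3)
        assert s.iloc[0] == pytest.approx(1.0)

    def test_set_outside_top_is_zero(self):
        x = np.array([[5.0, 4.0, 3.0, 2.0, 1.0, 0.9, 0.8, 0.7, 0.2, 0.1]])
        adata = adata_from_dense(x)
        s = tc.score_aucell(adata, GeneSet("s", ("g008", "g009")), top_fraction=0.3)
        assert s.iloc[0] == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(6)]
        for _ in range(25):
            x = rng.choice([0.0, 0.5, 1.0, 2.0], size=(1, 6))
            adata = adata_from_dense(x, genes)
            got = tc.score_aucell(adata, GeneSet("s", ("g000", "g002")), 0.5).iloc[0]
            want = aucell_oracle(x[0], genes, {"g000", "g002"}, 0.5)
            assert got == pytest.approx(want)

    def test_top_rank_below_one_rejected(self):
        adata = adata_from_dense(np.ones((1, 5)) * np.arange(5))
        with pytest.raises(ValueError):
            tc.score_aucell(adata, GeneSet("s", ("g000",)), top_fraction=0.0)


# ------------------------------------------------------------------ ucell


class TestUcell:
    def test_single_gene_rank_one(self):
        x = np.array([[99.0] + [float(i) for i in range(49)]])
        adata = adata_from_dense(x)
        s = tc.score_ucell(adata, GeneSet("s", ("g000",)), max_rank=30)
        assert s.iloc[0] == pytest.approx(1.0)

    def test_single_gene_beyond_max_rank(self):
        x = np.array([[0.0] + [float(i + 10) for i in range(49)]])
        adata = adata_from_dense(x)
        s = tc.score_ucell(adata, GeneSet("s", ("g000",)), max_rank=30)
        assert s.iloc[0] == 0.0

    def test_matches_pairwise_counting(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(50)]
        gene_set = ("g004", "g011", "g023", "g037", "g042")
        x = rng.normal(size=(1, 50))
        adata = adata_from_dense(x, genes)
        got = tc.score_ucell(adata, GeneSet("s", gene_set), max_rank=60).iloc[0]
        u = ucell_u_oracle(x[0], genes, set(gene_set))
        n_s = 5
        want = 1 - u / (n_s * (60 - n_s))
        assert got == pytest.approx(want)

    def test_set_too_large_rejected(self):
        adata = adata_from_dense(np.arange(10.0).reshape(1, 10))
        with pytest.raises(ValueError):
            tc.score_ucell(adata, GeneSet("s", tuple(adata.var_names[:5])), max_rank=5)


# -------------------------------------------------------------- singscore


class TestSingscore:
    def test_hand_arithmetic_top_two_of_ten(self):
        x = np.array([np.arange(10.0)])  # g009 highest ... g000 lowest
        adata = adata_from_dense(x)
        s = tc.score_singscore(adata, GeneSet("s", ("g008", "g009")))
        assert s.iloc[0] == pytest.approx((9.5 + 8.5) / 2 / 10 - 0.5)

    def test_whole_transcriptome_is_centered(self):
        rng = np.random.default_rng(4)
        adata = adata_from_dense(rng.normal(size=(5, 12)))
        s = tc.score_singscore(adata, GeneSet("all", tuple(adata.var_names)))
        assert np.allclose(s, 0.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(1.0, size=(10, 20))
        gene_set = GeneSet("s", ("g001", "g007", "g013"))
        a = tc.score_singscore(adata_from_dense(x), gene_set)
        b = tc.score_singscore(adata_from_dense(np.log1p(3 * x)), gene_set)
        assert np.allclose(a, b)


# ----------------------------------------------------------------- ssgsea


class TestSsgsea:
    def test_alpha_zero_matches_unweighted_ks_oracle(self):
        genes = [f"g{i:03d}" for i in range(8)]
        x = np.array([[5.0, 1.0, 4.0, 2.0, 3.0, 0.5, 6.0, 0.1]])
        adata = adata_from_dense(x, genes)
        got = tc.score_ssgsea(adata, GeneSet("s", ("g000", "g004")), alpha=0.0).iloc[0]
        want = ssgsea_oracle(x[0], genes, {"g000", "g004"}, alpha=0.0)
        assert got == pytest.approx(want)

    def test_general_alpha_matches_oracle(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i:03d}" for i in range(8)]
        for _ in range(20):
            x = rng.normal(size=(1, 8))
            got = tc.score_ssgsea(adata_from_dense(x, genes),
                                  GeneSet("s", ("g001", "g005", "g006")), 0.25).iloc[0]
            want = ssgsea_oracle(x[0], genes, {"g001", "g005", "g006"}, 0.25)
            assert got == pytest.approx(want)

    def test_bottom_set_is_negative(self):
        x = np.array([np.arange(10.0)[::-1]])  # g000 highest
        adata = adata_from_dense(x)
        s = tc.score_ssgsea(adata, GeneSet("s", ("g008", "g009")))
        assert s.iloc[0] < 0

    def test_identical_rankings_identical_scores(self):
        x = np.array([[1.0, 5.0, 3.0, 2.0], [10.0, 50.0, 30.0, 20.0]])
        adata = adata_from_dense(x)
        s = tc.score_ssgsea(adata, GeneSet("s", ("g001", "g002")))
        assert s.iloc[0] == pytest.approx(s.iloc[1])

    def test_whole_transcriptome_rejected(self):
        adata = adata_from_dense(np.arange(4.0).reshape(1, 4))
        with pytest.raises(ValueError):
            tc.score_ssgsea(adata, GeneSet("s", tuple(adata.var_names)))


# ------------------------------------------------------------ panel algebra


class TestPanelAlgebra:
    def test_normalized_columns_span_unit_interval(self, panel_sim):
        norm = panel_sim.normalized
        assert np.allclose(norm.min(axis=0), 0.0)
        assert np.allclose(norm.max(axis=0), 1.0)

    def test_constant_column_maps_to_half(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        norm = tc.normalize_panel(raw)
        assert np.allclose(norm["b"], 0.5)

    def test_zscore_then_minmax_equals_plain_minmax(self):
        rng = np.random.default_rng(7)
        raw = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        norm = tc.normalize_panel(raw)
        plain = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(norm.to_numpy(), plain.to_numpy())

    @pytest.mark.parametrize(
        "row,expected", [([1.0] * 5, 5.0), ([0.0] * 5, 0.0),
                         ([0.2, 0.4, 0.6, 0.8, 1.0], 3.0)]
    )
    def test_composite_row_sums(self, row, expected):
        norm = pd.DataFrame([row, [0.5] * 5], columns=list(tc.scoring.SCORE_COLUMNS))
        assert tc.composite_score(norm).iloc[0] == pytest.approx(expected)

    def test_row_alignment_preserved(self, panel_sim):
        assert panel_sim.raw.index.equals(panel_sim.normalized.index)
        assert panel_sim.raw.index.equals(panel_sim.scoring.index)


class TestScoreCorrelation:
    def test_self_correlation_and_antisorted(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 3.0, 2.0, 1.0]})
        corr = tc.score_correlation(raw)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing(self):
        raw = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        assert np.isnan(tc.score_correlation(raw).loc["a", "b"])

    def test_planted_simulation_all_positive(self, panel_sim):
        corr = tc.score_correlation(panel_sim.raw).to_numpy()
        off = corr[~np.eye(5, dtype=bool)]
        assert (off > 0).all()


class TestScoreInvariances:
    def test_gene_column_ordering_irrelevant(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(1.0, size=(8, 15))
        genes = [f"g{i:03d}" for i in range(15)]
        gene_set = GeneSet("s", ("g002", "g009"))
        perm = rng.permutation(15)
        a = adata_from_dense(x, genes)
        b = adata_from_dense(x[:, perm], [genes[i] for i in perm])
        for fn in (tc.score_aucell, tc.score_singscore, tc.score_ssgsea):
            assert np.allclose(fn(a, gene_set), fn(b, gene_set)), fn.__name__
        assert np.allclose(tc.score_ucell(a, gene_set, max_rank=12),
                           tc.score_ucell(b, gene_set, max_rank=12))

    def test_composite_separates_active_cells_across_effects(self):
        gaps = []
        for fc in (0.25, 0.75, 1.5):
            cfg = tc.SimConfig(n_patients_case=2, n_patients_control=2,
                               cells_per_patient=100, n_genes=200, n_risk_genes=15,
                               n_signature_genes=3, effect_log2fc=fc,
                               signature_log2fc=fc + 0.5, seed=21)
            sim = tc.simulate_dataset(cfg)
            panel = tc.score_panel(tc.lognormalize(sim.adata),
                                   sim.truth_risk_genes, seed=21)
            active = sim.adata.obs["truth_active"].to_numpy()
            gaps.append(panel.scoring[active].mean() - panel.scoring[~active].mean())
        assert all(g > 0 for g in gaps)
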