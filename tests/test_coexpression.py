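"""Bait-set co-expression score c(g,S), ranking and selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from mitocoex import (
    BaitSet,
    GeneSetCatalog,
    ModuleSpec,
    SimulationConfig,
    bait_coexpression_score,
    generate_design,
    generate_expression,
    group_score_distributions,
    normalize,
    pairwise_pearson,
    rank_and_cutoff,
    score_all,
)
from mitocoex.containers import CatalogError


def brute_force_score_table(matrix, bait_ids, include_self=False):
    """Double-loop oracle for c(g,S): scalar Pearson per pair, mean of the
    non-negative ones, empty set → 0."""
    rows = {}
    for g in matrix.gene_ids:
        x = matrix.data.loc[g].to_numpy()
        pos = []
        for b in bait_ids:
            if b == g and not include_self:
                continue
            y = matrix.data.loc[b].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            if denom == 0:
                continue
            rho = float(np.dot(xc, yc) / denom)
            if rho >= 0:
                pos.append(min(rho, 1.0))
        rows[g] = (float(np.mean(pos)) if pos else 0.0, len(pos))
    return rows


def profiles_with_exact_correlations(correlations, n_samples=8, seed=0):
    """Construct a probe profile plus baits whose Pearson correlation with
    the probe equals the requested values exactly (Gram–Schmidt)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    x -= x.mean()
    x /= np.linalg.norm(x)
    baits = []
    for i, c in enumerate(correlations):
        e = rng.standard_normal(n_samples)
        e -= e.mean()
        e -= np.dot(e, x) * x
        e /= np.linalg.norm(e)
        baits.append(c * x + np.sqrt(1 - c ** 2) * e)
    return x, np.array(baits)


class TestPairwisePearson:
    def test_identical_profile_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pairwise_pearson(x, x[None, :])[0] == pytest.approx(1.0)

    def test_negated_profile_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pairwise_pearson(x, (-x)[None, :])[0] == pytest.approx(-1.0)

    def test_matches_scalar_formula_oracle(self):
        g = np.array([1.0, 2.0, 3.0, 5.0])
        bait = np.array([2.0, 2.0, 4.0, 5.0])
        gc, bc = g - g.mean(), bait - bait.mean()
        expected = np.dot(gc, bc) / np.sqrt((gc ** 2).sum() * (bc ** 2).sum())
        assert pairwise_pearson(g, bait[None, :])[0] == pytest.approx(expected)

    def test_constant_profile_yields_nan(self):
        rho = pairwise_pearson(np.array([1.0, 2.0, 3.0]),
                               np.array([[4.0, 4.0, 4.0]]))
        assert np.isnan(rho[0])


class TestBaitScore:
    def test_duplicate_of_single_bait_scores_one(self):
        m = make_matrix([[1, 2, 3, 5], [1, 2, 3, 5]], genes=["g", "bait"])
        score, n_pos = bait_coexpression_score("g", BaitSet("S", ["bait"]), m)
        assert score == pytest.approx(1.0) and n_pos == 1

    def test_all_negative_correlations_score_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix([x, -x, -2 * x], genes=["g", "b1", "b2"])
        score, n_pos = bait_coexpression_score("g", BaitSet("S", ["b1", "b2"]), m)
        assert score == 0.0 and n_pos == 0

    def test_mean_of_positive_correlations(self):
        # baits at ρ = 0.8, 0.4, −0.5 → score (0.8+0.4)/2 = 0.6, n_pos 2
        x, baits = profiles_with_exact_correlations([0.8, 0.4, -0.5])
        m = make_matrix(np.vstack([x, baits]), genes=["g", "b1", "b2", "b3"])
        score, n_pos = bait_coexpression_score("g", BaitSet("S", ["b1", "b2", "b3"]), m)
        assert score == pytest.approx(0.6, abs=1e-12)
        assert n_pos == 2

    def test_missing_gene_raises(self):
        m = make_matrix([[1, 2, 3]], genes=["a"])
        with pytest.raises(KeyError):
            bait_coexpression_score("nope", BaitSet("S", ["a"]), m)

    def test_self_exclusion_default_and_override(self):
        x, baits = profiles_with_exact_correlations([0.5], seed=3)
        m = make_matrix(np.vstack([x, baits]), genes=["b0", "b1"])
        s = BaitSet("S", ["b0", "b1"])
        score_excl, n_excl = bait_coexpression_score("b0", s, m)
        score_incl, n_incl = bait_coexpression_score("b0", s, m, include_self=True)
        assert (score_excl, n_excl) == (pytest.approx(0.5), 1)
        assert score_incl == pytest.approx(0.75) and n_incl == 2


class TestScoreAll:
    def test_mutually_identical_baits_all_score_one(self):
        row = np.array([1.0, 2.0, 4.0, 3.0])
        m = make_matrix([row, 2 * row, row + 1], genes=["b1", "b2", "b3"])
        table = score_all(m, BaitSet("S", ["b1", "b2", "b3"]), universe="all")
        assert np.allclose(table["score"], 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(0, 1, size=(50, 8)) + 2)
        baits = BaitSet("S", [f"g{i}" for i in range(0, 10)])
        table = score_all(m, baits, universe="all")
        oracle = brute_force_score_table(m, baits.members)
        for g in m.gene_ids:
            assert table.at[g, "score"] == pytest.approx(oracle[g][0], abs=1e-12)
            assert table.at[g, "n_pos"] == oracle[g][1]

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_property_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(5, 40))
        n_samples = int(rng.integers(4, 10))
        n_baits = int(rng.integers(1, n_genes))
        m = make_matrix(rng.normal(0, 1, size=(n_genes, n_samples)))
        baits = BaitSet("S", [f"g{i}" for i in range(n_baits)])
        table = score_all(m, baits, universe="all")
        oracle = brute_force_score_table(m, baits.members)
        for g in m.gene_ids:
            assert table.at[g, "score"] == pytest.approx(oracle[g][0], abs=1e-12)
        assert ((table["score"] >= 0) & (table["score"] <= 1)).all()

    def test_affine_invariance_of_scores(self):
        rng = np.random.default_rng(17)
        values = rng.normal(0, 1, size=(12, 8))
        m1 = make_matrix(values)
        values2 = values.copy()
        values2[5] = 3.0 * values2[5] + 7.0  # positive affine map of one gene
        m2 = make_matrix(values2)
        baits = BaitSet("S", ["g0", "g1", "g2"])
        t1 = score_all(m1, baits, universe="all")
        t2 = score_all(m2, baits, universe="all")
        assert np.allclose(t1["score"], t2["score"], atol=1e-12)

    def test_nuclear_universe_excludes_mito_rows(self):
        rng = np.random.default_rng(18)
        origin = ["nuclear"] * 8 + ["mitochondrial"] * 2
        m = make_matrix(rng.normal(size=(10, 6)), origin=origin)
        table = score_all(m, BaitSet("S", ["g0", "g1"]))
        assert len(table) == 8 and "g8" not in table.index

    def test_planted_module_scores_above_background(self, planted_dataset, planted_centered):
        module = planted_dataset.module_genes("module1")
        baits = BaitSet("bait", module[:20])
        table = score_all(planted_centered, baits)
        held = [g for g in module[20:] if g in table.index]
        background = table.drop(index=[g for g in module if g in table.index])
        assert table.loc[held, "score"].median() > background["score"].median()

    def test_monotone_recovery_in_loading(self):
        medians = []
        for loading in (0.3, 0.8, 1.5):
            cfg = SimulationConfig(n_genes=300,
                                   module_specs=(ModuleSpec(30, loading, "m"),),
                                   seed=99)
            res = generate_expression(generate_design(cfg), cfg)
            centered = normalize(res.matrix)
            table = score_all(centered, BaitSet("S", res.module_genes("m")[:10]))
            held = res.module_genes("m")[10:]
            medians.append(table.loc[held, "score"].median())
        assert medians[0] <= medians[1] <= medians[2]


class TestRankAndCutoff:
    def test_floor_count_at_paper_scale(self):
        rng = np.random.default_rng(30)
        table = pd.DataFrame({"score": rng.uniform(0, 1, 13_684)},
                             index=[f"g{i:05d}" for i in range(13_684)])
        out, cutoff = rank_and_cutoff(table, 0.05)
        assert int(out["selected"].sum()) == 684
        assert cutoff == pytest.approx(out.loc[out["selected"], "score"].min())

    def test_top_five_of_hundred_distinct(self):
        scores = np.linspace(0, 1, 100)
        table = pd.DataFrame({"score": scores}, index=[f"g{i:03d}" for i in range(100)])
        out, _ = rank_and_cutoff(table, 0.05)
        assert set(out.index[out["selected"]]) == set(table.sort_values("score").index[-5:])

    def test_boundary_ties_resolved_by_gene_id(self):
        table = pd.DataFrame(
            {"score": [0.9, 0.5, 0.5, 0.5, 0.1, 0.0]},
            index=["gF", "gC", "gA", "gB", "gD", "gE"],
        )
        out, cutoff = rank_and_cutoff(table, 0.5)  # floor(3) selected
        # sort oracle: descending score, ascending id among the 0.5 ties
        assert set(out.index[out["selected"]]) == {"gF", "gA", "gB"}
        assert cutoff == pytest.approx(0.5)

    def test_empty_selection_rejected(self):
        table = pd.DataFrame({"score": [0.5] * 10})
        with pytest.raises(ValueError):
            rank_and_cutoff(table, 0.01)


class TestGroupDistributions:
    def test_single_group_equals_global_summary(self):
        rng = np.random.default_rng(31)
        table = pd.DataFrame({"score": rng.uniform(0, 1, 20)},
                             index=[f"g{i}" for i in range(20)])
        catalog = GeneSetCatalog({"all": list(table.index)})
        summary = group_score_distributions(table, catalog)
        assert summary.at["all", "median"] == pytest.approx(table["score"].median())
        assert summary.at["all", "n"] == 20

    def test_singleton_groups_report_own_scores(self):
        table = pd.DataFrame({"score": [0.2, 0.8]}, index=["a", "b"])
        catalog = GeneSetCatalog({"A": ["a"], "B": ["b"]})
        summary = group_score_distributions(table, catalog)
        assert summary.at["A", "median"] == pytest.approx(0.2)
        assert summary.at["B", "median"] == pytest.approx(0.8)

    def test_overlapping_groups_rejected(self):
        table = pd.DataFrame({"score": [0.2, 0.8]}, index=["a", "b"])
        catalog = GeneSetCatalog({"A": ["a", "b"], "B": ["b"]})
        with pytest.raises(CatalogError):
            group_score_distributions(table, catalog)

    def test_planted_shift_orders_group_medians(self):
        rng = np.random.default_rng(32)
        low = rng.uniform(0.0, 0.2, 30)
        mid = rng.uniform(0.3, 0.5, 30)
        high = rng.uniform(0.6, 0.9, 30)
        genes = [f"g{i}" for i in range(90)]
        table = pd.DataFrame({"score": np.concatenate([low, mid, high])}, index=genes)
        catalog = GeneSetCatalog({"low": genes[:30], "mid": genes[30:60], "high": genes[60:]})
        summary = group_score_distributions(table, catalog)
        assert summary.at["low", "median"] < summary.at["mid", "median"] < summary.at["high", "median"]
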