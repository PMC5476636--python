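"""Gene-pair Bayes scores and marker-set mean scores."""

import numpy as np
import pandas as pd
import pytest

import recat
from recat.matrix import ExpressionMatrix, ValidationError
from recat.scores import (
    GenePairModel,
    MeanScoreSets,
    bayes_scores,
    mean_scores,
    score_track,
    train_gene_pairs,
)


def _log_mat(values, genes, cells):
    mat = ExpressionMatrix(values, genes, cells)
    return mat.with_layer(np.asarray(values, float), "normalized").with_layer(
        np.asarray(values, float), "log2"
    )


def _model(pairs, probs):
    return GenePairModel(pairs=pairs, probs={s: np.asarray(p) for s, p in probs.items()})


class TestTraining:
    def test_laplace_smoothing_hand_count(self):
        # stage G1: 3/4 cells with e_a >= e_b  ->  p = (3+1)/(4+2) = 2/3
        a = [5, 5, 5, 1, 1, 5, 1, 1, 1, 5, 1, 1]
        b = [2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2]
        labels = ["G1"] * 4 + ["S"] * 4 + ["G2M"] * 4
        mat = _log_mat(np.array([a, b], dtype=float), ["ga", "gb"],
                       [f"c{i}" for i in range(12)])
        model = train_gene_pairs(mat, np.array(labels), pairs_per_stage=1)
        i = model.pairs.index(("ga", "gb"))
        assert model.probs["G1"][i] == pytest.approx((3 + 1) / (4 + 2))

    def test_uninformative_pair_never_selected(self):
        # identical relation in all stages -> margin 0 everywhere
        values = np.array([[3.0] * 6, [1.0] * 6])
        labels = ["G1", "G1", "S", "S", "G2M", "G2M"]
        mat = _log_mat(values, ["ga", "gb"], [f"c{i}" for i in range(6)])
        with pytest.raises(ValidationError, match="no informative"):
            train_gene_pairs(mat, np.array(labels), pairs_per_stage=5)

    def test_invariant_to_monotone_transform(self, small_log):
        mat, truth, _ = small_log
        labels = np.array(truth.stage)
        m1 = train_gene_pairs(mat, labels, pairs_per_stage=20)
        squashed = ExpressionMatrix(
            np.sqrt(mat.values), mat.gene_ids, mat.cell_ids, mat.unit, "raw"
        ).with_layer(np.sqrt(mat.values), "normalized").with_layer(np.sqrt(mat.values), "log2")
        m2 = train_gene_pairs(squashed, labels, pairs_per_stage=20)
        assert m1.pairs == m2.pairs
        for s in ("G1", "S", "G2M"):
            np.testing.assert_allclose(m1.probs[s], m2.probs[s])

    def test_shipped_default_model_loads(self):
        from recat.scores import load_default_pair_model

        model = load_default_pair_model()
        assert model.n_pairs > 0
        assert sum(model.priors.values()) == pytest.approx(1.0)
        for s in ("G1", "S", "G2M"):
            assert np.all((model.probs[s] > 0) & (model.probs[s] < 1))

    def test_json_round_trip(self, small_log):
        mat, truth, _ = small_log
        model = train_gene_pairs(mat, np.array(truth.stage), pairs_per_stage=10)
        back = GenePairModel.from_json(model.to_json())
        assert back.pairs == model.pairs
        np.testing.assert_allclose(back.probs["S"], model.probs["S"])


class TestBayesScores:
    def test_uninformative_model_equal_scores(self):
        model = _model([("a", "b"), ("c", "d")],
                       {s: [0.5, 0.5] for s in ("G1", "S", "G2M")})
        expr = pd.Series({"a": 1.0, "b": 0.0, "c": 0.0, "d": 1.0})
        scores = bayes_scores(model, expr)
        expected = 2 * np.log10(0.5) + np.log10(1 / 3)
        np.testing.assert_allclose(scores, expected)

    def test_hand_computed_score(self):
        # N_p = 2, p = (0.9, 0.8) for G1, x = (1, 1)
        model = _model(
            [("a", "b"), ("c", "d")],
            {"G1": [0.9, 0.8], "S": [0.5, 0.5], "G2M": [0.5, 0.5]},
        )
        expr = pd.Series({"a": 2.0, "b": 1.0, "c": 3.0, "d": 1.0})
        scores = bayes_scores(model, expr)
        assert scores[0] == pytest.approx(np.log10(0.9 * 0.8 / 3))

    def test_pair_order_invariance(self):
        p1 = _model([("a", "b"), ("c", "d")], {"G1": [0.9, 0.2], "S": [0.4, 0.6], "G2M": [0.3, 0.7]})
        p2 = _model([("c", "d"), ("a", "b")], {"G1": [0.2, 0.9], "S": [0.6, 0.4], "G2M": [0.7, 0.3]})
        expr = pd.Series({"a": 2.0, "b": 1.0, "c": 0.0, "d": 1.0})
        np.testing.assert_allclose(bayes_scores(p1, expr), bayes_scores(p2, expr))

    def test_missing_gene_named(self):
        model = _model([("a", "zz")], {s: [0.6] for s in ("G1", "S", "G2M")})
        with pytest.raises(ValidationError, match="zz"):
            bayes_scores(model, pd.Series({"a": 1.0}))

    def test_scores_bounded_by_log_prior(self, small_log):
        mat, truth, _ = small_log
        model = train_gene_pairs(mat, np.array(truth.stage), pairs_per_stage=10)
        expr = mat.to_frame().iloc[:, 0]
        scores = bayes_scores(model, expr)
        assert np.all(scores <= np.log10(1 / 3) + 1e-12)


class TestMeanScores:
    SETS = MeanScoreSets(
        {"G1": ["g1"], "G1/S": ["g2"], "S": ["g3"], "G2": ["g4"], "G2/M": ["g5"], "M": ["g1", "g3"]}
    )

    def test_zero_expression_zero_scores(self):
        expr = pd.Series(0.0, index=[f"g{i}" for i in range(1, 6)])
        np.testing.assert_allclose(mean_scores(expr, self.SETS), 0.0)

    def test_set_mean(self):
        expr = pd.Series({"g1": 2.0, "g2": 0.0, "g3": 4.0, "g4": 0.0, "g5": 0.0})
        out = mean_scores(expr, self.SETS)
        assert out[5] == pytest.approx(3.0)  # M set {g1, g3} -> (2+4)/2

    def test_locality(self):
        expr = pd.Series({"g1": 2.0, "g2": 1.0, "g3": 4.0, "g4": 3.0, "g5": 5.0})
        bumped = expr.copy()
        bumped["g4"] *= 2  # disjoint from the G1 set
        assert mean_scores(expr, self.SETS)[0] == mean_scores(bumped, self.SETS)[0]

    def test_empty_stage_set_raises(self):
        expr = pd.Series({"g1": 1.0})
        with pytest.raises(ValidationError, match="no marker genes"):
            mean_scores(expr, self.SETS)


class TestScoreTrack:
    def test_track_length_and_reversal(self, small_log):
        mat, truth, catalog = small_log
        sets = MeanScoreSets.from_catalog(catalog)
        model = train_gene_pairs(mat, np.array(truth.stage), pairs_per_stage=20)
        order = recat.ConsensusOrder(truth.phi, mat.cell_ids)
        track = score_track(order, mat, model, sets)
        assert len(track) == mat.n_cells
        rev = track.reversed()
        np.testing.assert_allclose(rev.scores, track.scores[::-1])
        assert rev.unit_ids == track.unit_ids[::-1]

    def test_g1s_peak_precedes_g2m_peak(self, small_log):
        # on synthetic data ordered by true phase, the G1/S mean-score peaks
        # earlier in the cycle than the G2/M mean-score
        mat, truth, catalog = small_log
        sets = MeanScoreSets.from_catalog(catalog)
        model = train_gene_pairs(mat, np.array(truth.stage), pairs_per_stage=20)
        order = recat.ConsensusOrder(truth.phi, mat.cell_ids)
        track = score_track(order, mat, model, sets)
        from recat.methylation import smooth9

        g1s = smooth9(track.scores[:, 4], window=15)
        g2m = smooth9(track.scores[:, 7], window=15)
        assert np.argmax(g1s) < np.argmax(g2m)

    def test_g0_depresses_all_mean_scores(self):
        cfg = recat.CycleSimConfig(n_cells=200, n_genes=150, seed=9, g0_fraction=0.25)
        mat, truth = recat.simulate_expression(cfg)
        from recat.preprocess import log_transform, normalize, subset_to_catalog

        catalog = recat.make_catalog(truth)
        m = subset_to_catalog(log_transform(normalize(mat)), catalog)
        sets = MeanScoreSets.from_catalog(catalog)
        df = m.to_frame()
        g0_cells = [c for c, s in zip(m.cell_ids, truth.stage) if s == "G0"]
        other = [c for c, s in zip(m.cell_ids, truth.stage) if s != "G0"]
        g0_scores = np.mean([mean_scores(df[c], sets) for c in g0_cells], axis=0)
        other_scores = np.mean([mean_scores(df[c], sets) for c in other], axis=0)
        assert np.all(g0_scores < other_scores)
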