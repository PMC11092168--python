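import itertools

import numpy as np
import pandas as pd
import pytest

from mvboost.boosting import (
    Ensemble,
    WeakHypothesis,
    WeakRound,
    agreement_indicator,
    compute_alpha,
    compute_edge,
    fit_irboost,
    fit_rboost_binary,
    make_base_learner,
    modified_predict,
    modified_proba,
    predict_ensemble,
    update_weights,
)
from mvboost.data_model import (
    IntegrityError,
    LabelEncoding,
    ParameterError,
    UnpredictableError,
    ViewTable,
    assemble_dataset,
)
from mvboost.synthetic_data import SyntheticSpec, ViewSpec, generate


class TestAgreement:
    @pytest.mark.parametrize(
        "a,b,expected", [(2, 2, 1), (1, 0, 0), (3, 1, 0), (0, 0, 1)]
    )
    def test_indicator(self, a, b, expected):
        assert agreement_indicator(a, b) == expected


class TestAlpha:
    def test_zero_edge(self):
        assert compute_alpha(0.0) == 0.0

    def test_closed_form(self):
        assert compute_alpha(0.4) == pytest.approx(0.5 * np.log(1.4 / 0.6))
        assert compute_alpha(0.4) == pytest.approx(0.4236, abs=1e-4)

    def test_perfect_edge_clipped_finite(self):
        a = compute_alpha(1.0)
        assert np.isfinite(a) and a == pytest.approx(
            0.5 * np.log((2 - 1e-10) / 1e-10)
        )

    def test_odd_symmetry(self):
        assert compute_alpha(-0.4) == pytest.approx(-compute_alpha(0.4))


class TestEdge:
    def test_all_correct_equals_weight_mass(self):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        y = np.array([1, 2, 1, 2])
        assert compute_edge(w, y, y) == pytest.approx(1.0)

    def test_weighted_hand_value(self):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        y = np.array([1, 1, 2, 2])
        pred = np.array([1, 1, 1, 1])  # correct on the first two only
        assert compute_edge(w, pred, y) == pytest.approx(0.4)

    def test_absent_samples_contribute_zero(self):
        w = np.array([0.5, 0.5])
        y = np.array([1, 2])
        pred = np.array([1, 0])  # second sample absent -> artificial 0
        mask = np.array([True, False])
        assert compute_edge(w, pred, y, mask) == pytest.approx(0.5)

    def test_binary_identity_exhaustive(self):
        """sum w_i y_i h_i == 2 sum w_i (I - 1/2) for every labeling, exactly."""
        rng = np.random.default_rng(0)
        for n in (2, 4, 6):
            w = rng.random(n)
            w /= w.sum()
            for y in itertools.product((-1.0, 1.0), repeat=n):
                y = np.array(y)
                h = -y if n == 2 else np.roll(y, 1)
                lhs = float(np.sum(w * y * h))
                ind = (y == h).astype(float)
                rhs = float(np.sum(w * 2 * (ind - 0.5)))
                assert lhs == rhs  # bit-exact, not approx


class TestUpdateWeights:
    def test_zero_alpha_is_identity(self):
        w = np.array([0.25, 0.75])
        out = update_weights(w, 0.0, np.array([1.0, -1.0]))
        np.testing.assert_array_equal(out, w)

    def test_hand_value_one_right_one_wrong(self):
        w = np.array([0.5, 0.5])
        sgn = np.array([1.0, -1.0])  # first correct, second wrong
        out = update_weights(w, 0.5, sgn)
        np.testing.assert_allclose(out, [0.26894142, 0.73105858], atol=1e-8)

    def test_absent_weight_changes_only_via_renormalization(self):
        w = np.array([0.25, 0.25, 0.5])
        mask = np.array([True, True, False])
        sgn = np.array([1.0, -1.0, 1.0])
        out = update_weights(w, 0.7, sgn, mask)
        # the absent sample's unnormalized weight is untouched
        ratio = out[2] / w[2]
        expected_norm = (
            w[0] * np.exp(-0.7) + w[1] * np.exp(0.7) + w[2]
        )
        assert ratio == pytest.approx(1.0 / expected_norm)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class _StubModel:
    """Deterministic fake classifier for combination-rule tests."""

    def __init__(self, proba_by_row, classes):
        self._p = np.asarray(proba_by_row)
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return self.classes_[np.argmax(self._p[: len(X)], axis=1)]

    def predict_proba(self, X):
        return self._p[: len(X)]


def _stub_hypothesis(view, proba, classes, n_classes):
    return WeakHypothesis(
        view_id=view.view_id,
        model=_StubModel(proba, classes),
        feature_ids=view.feature_ids,
        n_classes=n_classes,
        classes_seen=np.asarray(classes),
    )


class TestModifiedPredictions:
    def test_absent_sample_gets_artificial_label_and_zero_vector(self):
        view = ViewTable("v", pd.DataFrame({"f": [1.0]}, index=["a"]))
        h = _stub_hypothesis(view, [[0.2, 0.8]], [1, 2], 2)
        assert modified_predict(h, view, "ghost") == 0
        np.testing.assert_array_equal(modified_proba(h, view, "ghost"), [0.0, 0.0])

    def test_present_sample_passes_through(self):
        view = ViewTable("v", pd.DataFrame({"f": [1.0]}, index=["a"]))
        h = _stub_hypothesis(view, [[0.2, 0.8]], [1, 2], 2)
        assert modified_predict(h, view, "a") == 2
        v = modified_proba(h, view, "a")
        assert v.sum() == pytest.approx(1.0) and v[1] == 0.8

    def test_proba_expanded_to_full_class_space(self):
        view = ViewTable("v", pd.DataFrame({"f": [1.0]}, index=["a"]))
        h = _stub_hypothesis(view, [[1.0]], [3], 4)  # single-class training slice
        v = modified_proba(h, view, "a")
        np.testing.assert_array_equal(v, [0.0, 0.0, 1.0, 0.0])


class TestPredictCombination:
    def _toy_ensemble(self, proba_rows, alphas, n_classes=3):
        view = ViewTable(
            "v", pd.DataFrame({"f": [0.0]}, index=["a"])
        )
        rounds = [
            WeakRound(
                t=i, view_id="v", j=0,
                hypothesis=_stub_hypothesis(view, [p], list(range(1, n_classes + 1)),
                                            n_classes),
                edge=0.5, alpha=al,
            )
            for i, (p, al) in enumerate(zip(proba_rows, alphas))
        ]
        enc = LabelEncoding.fit(list(range(1, n_classes + 1)))
        ens = Ensemble(kind="irboost", rounds=rounds, encoding=enc,
                       n_classes=n_classes,
                       winner_counts={"v": len(rounds)}, T=len(rounds))
        ds = assemble_dataset([view], {"a": 1})
        return ens, ds

    def test_single_round_returns_base_argmax(self):
        ens, ds = self._toy_ensemble([[0.1, 0.7, 0.2]], [1.0])
        labels, scores = predict_ensemble(ens, ds)
        assert labels == [2]
        np.testing.assert_allclose(scores[0], [0.1, 0.7, 0.2])

    def test_tie_breaks_toward_smallest_class(self):
        ens, ds = self._toy_ensemble([[0.4, 0.4, 0.2]], [1.0])
        labels, _ = predict_ensemble(ens, ds)
        assert labels == [1]

    def test_zero_alpha_rounds_excluded(self):
        ens, ds = self._toy_ensemble(
            [[0.1, 0.7, 0.2], [1.0, 0.0, 0.0]], [1.0, 0.0]
        )
        labels, scores = predict_ensemble(ens, ds)
        assert labels == [2]
        np.testing.assert_allclose(scores[0], [0.1, 0.7, 0.2])

    def test_unpredictable_instance_raises(self):
        ens, ds = self._toy_ensemble([[0.5, 0.3, 0.2]], [1.0])
        view2 = ViewTable("w", pd.DataFrame({"g": [1.0]}, index=["b"]))
        ds2 = assemble_dataset([ds.views[0], view2], {"a": 1, "b": 2})
        from mvboost.data_model import restrict_to_samples

        only_b = restrict_to_samples(ds2, ["b"])
        with pytest.raises(UnpredictableError):
            predict_ensemble(ens, only_b)


def _complete_binary(seed, n=40, K=2, q=4):
    spec = SyntheticSpec(
        n_samples=n, n_classes=2,
        views=tuple(ViewSpec(q, 1.5, 0.0) for _ in range(K)), seed=seed,
    )
    return generate(spec)[0]


class TestFitLoops:
    def test_single_view_wins_every_round(self):
        spec = SyntheticSpec(n_samples=30, n_classes=2,
                             views=(ViewSpec(3, 2.0, 0.0),), seed=0)
        ds, _ = generate(spec)
        ens = fit_irboost(ds, T=7, base_learner="dt-2", seed=0)
        assert ens.winner_counts == {"view1": 7}
        assert sum(ens.winner_counts.values()) == ens.T

    def test_fixed_seed_bit_identical_winner_sequence(self):
        ds = _complete_binary(3)
        a = fit_irboost(ds, T=12, base_learner="dt-2", seed=5)
        b = fit_irboost(ds, T=12, base_learner="dt-2", seed=5)
        assert [r.view_id for r in a.rounds] == [r.view_id for r in b.rounds]
        assert [r.edge for r in a.rounds] == [r.edge for r in b.rounds]

    def test_weights_and_probabilities_normalized_every_iteration(self):
        ds = _complete_binary(1)
        ens = fit_irboost(ds, T=10, base_learner="dt-1", seed=2,
                          record_weights=True)
        for entry in ens.trace:
            assert abs(sum(entry["w"]) - 1.0) <= 1e-12
            assert abs(sum(entry["p"]) - 1.0) <= 1e-12
            assert abs(entry["edge"]) <= 1.0 + 1e-12

    def test_rboost_requires_binary_complete(self):
        spec = SyntheticSpec(n_samples=30, n_classes=3,
                             views=(ViewSpec(4, 2.0, 0.0),), seed=0)
        ds3, _ = generate(spec)
        with pytest.raises(ParameterError, match="fit_irboost"):
            fit_rboost_binary(ds3, T=3)
        spec_inc = SyntheticSpec(n_samples=40, n_classes=2,
                                 views=(ViewSpec(4, 2.0, 0.0),
                                        ViewSpec(4, 2.0, 0.4)), seed=0)
        ds_inc, _ = generate(spec_inc)
        with pytest.raises(IntegrityError, match="complete"):
            fit_rboost_binary(ds_inc, T=3)

    def test_oracle_equivalence_single_dataset(self):
        """Complete binary data: both loops produce identical trajectories."""
        ds = _complete_binary(7, n=50, K=3)
        a = fit_irboost(ds, T=15, base_learner="rf-10", seed=11,
                        record_weights=True)
        b = fit_rboost_binary(ds, T=15, base_learner="rf-10", seed=11,
                              record_weights=True)
        assert [r.view_id for r in a.rounds] == [r.view_id for r in b.rounds]
        assert [r.edge for r in a.rounds] == [r.edge for r in b.rounds]
        assert [e["w"] for e in a.trace] == [e["w"] for e in b.trace]

    def test_separable_problem_reaches_zero_training_error(self):
        spec = SyntheticSpec(n_samples=40, n_classes=2,
                             views=(ViewSpec(2, 8.0, 0.0),), seed=4)
        ds, _ = generate(spec)
        ens = fit_rboost_binary(ds, T=10, base_learner="dt-1", seed=0)
        labels, _ = predict_ensemble(ens, ds)
        assert all(l == ds.labels[s] for l, s in zip(labels, ds.all_samples))

    def test_label_flip_symmetry(self):
        ds = _complete_binary(9, n=40, K=1)
        ens = fit_rboost_binary(ds, T=8, base_learner="dt-1", seed=3)
        labels, _ = predict_ensemble(ens, ds)
        acc = np.mean([l == ds.labels[s] for l, s in zip(labels, ds.all_samples)])

        flipped = {s: 3 - c for s, c in ds.labels.items()}  # 1<->2
        ds_f = assemble_dataset(ds.views, flipped)
        ens_f = fit_rboost_binary(ds_f, T=8, base_learner="dt-1", seed=3)
        labels_f, _ = predict_ensemble(ens_f, ds_f)
        acc_f = np.mean(
            [l == ds_f.labels[s] for l, s in zip(labels_f, ds_f.all_samples)]
        )
        assert acc == pytest.approx(acc_f)

    def test_absent_view_prediction_uses_present_view_only(self):
        spec = SyntheticSpec(n_samples=50, n_classes=2,
                             views=(ViewSpec(4, 2.5, 0.0), ViewSpec(4, 2.5, 0.5)),
                             seed=6)
        ds, _ = generate(spec)
        ens = fit_irboost(ds, T=10, base_learner="dt-2", seed=1)
        labels, scores = predict_ensemble(ens, ds)
        assert scores.shape == (ds.n_samples, 2)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        ds = _complete_binary(2, n=30, K=2)
        ens = fit_irboost(ds, T=5, base_learner="dt-2", seed=0)
        ens.save(tmp_path / "model")
        back = Ensemble.load(tmp_path / "model")
        assert back.kind == ens.kind and back.T == ens.T
        assert back.winner_counts == ens.winner_counts
        l1, s1 = predict_ensemble(ens, ds)
        l2, s2 = predict_ensemble(back, ds)
        assert l1 == l2
        np.testing.assert_array_equal(s1, s2)


def test_base_learner_factory():
    rf = make_base_learner("rf", 0)
    assert rf.n_estimators == 50
    assert make_base_learner("rf-7", 0).n_estimators == 7
    assert make_base_learner("dt-3", 0).max_depth == 3
    with pytest.raises(ParameterError):
        make_base_learner("svm", 0)
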