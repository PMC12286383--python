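"""Training-loop mechanics: loss assembly, determinism, inference ensemble."""

import math
import warnings

import numpy as np
import pytest

from camsda.autodiff import Tensor
from camsda.class_aware import class_aware_loss
from camsda.moments import alignment_loss, compute_moments, pair_distance
from camsda.networks import ModelBundle
from camsda.synthetic import DomainDataset
from camsda.training import (
    NotFittedError,
    TrainConfig,
    TrainingDivergenceError,
    classification_loss,
    fit,
    predict_target,
    total_loss,
    train_step,
)
from camsda.weighting import WeightState, contribution_weights

from conftest import tiny_scenario


# --- classification loss -----------------------------------------------

def test_confident_correct_classifiers_have_zero_loss():
    probs = [np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[0.0, 1.0]])]
    labels = [np.array([0, 1]), np.array([1])]
    assert classification_loss(probs, labels) == pytest.approx(0.0)


def test_classification_loss_sums_over_domains():
    probs = [np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])]
    labels = [np.array([0]), np.array([1])]
    assert classification_loss(probs, labels) == pytest.approx(2 * math.log(2))


def test_single_domain_reduces_to_cross_entropy(rng):
    probs = rng.dirichlet(np.ones(3), size=5)
    labels = rng.integers(0, 3, size=5)
    assert classification_loss([probs], [labels]) == pytest.approx(
        class_aware_loss(probs, labels)
    )


def test_classification_loss_rejects_out_of_range_label():
    with pytest.raises(ValueError):
        classification_loss([np.array([[0.5, 0.5]])], [np.array([2])])


# --- total loss ---------------------------------------------------------

def test_total_loss_examples():
    assert total_loss(0.0, 0.0, 0.0) == 0.0
    assert total_loss(0.5, 1.25, 2.0) == pytest.approx(3.75)
    assert total_loss(0.5, 1.25, 2.0, coefficients=(1.0, 0.0, 1.0)) == pytest.approx(2.5)


def test_total_loss_rejects_non_finite_components():
    with pytest.raises(TrainingDivergenceError):
        total_loss(float("nan"), 0.0, 0.0)


# --- train_step ---------------------------------------------------------

def make_batches(scenario, m=16, seed=0):
    sources, target, _ = scenario
    rng = np.random.default_rng(seed)
    src = []
    for d in sources:
        idx = rng.choice(len(d), size=m, replace=False)
        src.append((d.values[idx], d.labels[idx]))
    t_idx = rng.choice(len(target), size=m, replace=False)
    return src, target.values[t_idx]


def build_bundle(scenario, config):
    sources, _, _ = scenario
    return ModelBundle.build(
        n_domains=len(sources),
        n_classes=4,
        input_dim=sources[0].values.shape[1],
        feature_dim=config.feature_dim,
        hidden_dim=config.hidden_dim,
        seed=config.seed,
    )


def test_logged_total_matches_independent_recomputation(small_scenario):
    """Frozen-parameter oracle: the record equals the sum of separately computed losses."""
    config = TrainConfig(n_iterations=1, seed=3, feature_dim=16, hidden_dim=32)
    bundle = build_bundle(small_scenario, config)
    src_batches, target_values = make_batches(small_scenario)

    # recompute the three losses from the same frozen parameters
    feats = [bundle.features(v) for v, _ in src_batches]
    ft = bundle.features(target_values)
    q = bundle.label_map.n_classes
    l_class = np.mean(
        [
            float(class_aware_loss(bundle.class_aware_head(f), i * q + lbl))
            for i, (f, (_, lbl)) in enumerate(zip(feats, src_batches))
        ]
    )
    tm = compute_moments(ft.data)
    dist = np.array([pair_distance(compute_moments(f.data), tm) for f in feats])
    state = contribution_weights(dist)
    l_awmd = float(alignment_loss([f.data for f in feats], ft.data, state).total)
    l_cls = float(
        classification_loss(
            [clf(f).data for clf, f in zip(bundle.classifiers, feats)],
            [lbl for _, lbl in src_batches],
        )
    )
    record, _ = train_step(bundle, src_batches, target_values, config)
    assert record.l_total == pytest.approx(l_class + l_awmd + l_cls, rel=1e-6)
    assert record.l_total == pytest.approx(
        record.l_class + record.l_awmd + record.l_cls, rel=1e-9
    )
    assert record.l_awmd == pytest.approx(record.l_ss + record.l_st, rel=1e-9)


def test_ablated_step_keeps_log_identity(small_scenario):
    config = TrainConfig(
        n_iterations=1, seed=3, feature_dim=16, hidden_dim=32,
        use_class_aware=False, use_reweighting=False,
    )
    bundle = build_bundle(small_scenario, config)
    src_batches, target_values = make_batches(small_scenario)
    record, state = train_step(bundle, src_batches, target_values, config)
    assert record.l_class == 0.0
    assert np.allclose(state.w, 0.5)  # uniform weights under the ablation
    assert record.l_total == pytest.approx(record.l_class + record.l_awmd + record.l_cls)


def test_batch_size_mismatch_rejected(small_scenario):
    config = TrainConfig(n_iterations=1, seed=0, feature_dim=8, hidden_dim=16)
    bundle = build_bundle(small_scenario, config)
    src_batches, target_values = make_batches(small_scenario)
    bad = [(src_batches[0][0][:8], src_batches[0][1][:8]), src_batches[1]]
    with pytest.raises(ValueError):
        train_step(bundle, bad, target_values, config)


# --- fit -----------------------------------------------------------------

def test_fit_one_iteration_produces_one_record(small_scenario):
    sources, target, _ = small_scenario
    config = TrainConfig(n_iterations=1, seed=0, feature_dim=8, hidden_dim=16, batch_size=8)
    bundle = build_bundle(small_scenario, config)
    bundle, log, weights, relevance = fit(bundle, sources, target, config)
    assert len(log) == 1
    assert bundle.fitted
    assert weights.w.shape == (2,)
    assert relevance is not None and len(relevance) == 2


def test_fit_is_deterministic_for_fixed_seed(small_scenario):
    sources, target, _ = small_scenario
    config = TrainConfig(n_iterations=10, seed=42, feature_dim=8, hidden_dim=16, batch_size=8)
    logs = []
    for _ in range(2):
        bundle = build_bundle(small_scenario, config)
        _, log, _, _ = fit(bundle, sources, target, config)
        logs.append(np.array([r.row() for r in log]))
    assert np.abs(logs[0] - logs[1]).max() < 1e-10


def test_total_loss_decreases_over_training(small_scenario):
    sources, target, _ = small_scenario
    config = TrainConfig(n_iterations=300, seed=1, feature_dim=16, hidden_dim=32, batch_size=16)
    bundle = build_bundle(small_scenario, config)
    _, log, _, _ = fit(bundle, sources, target, config)
    totals = [r.l_total for r in log]
    assert np.mean(totals[-100:]) < np.mean(totals[:100])


def test_small_domain_triggers_replacement_warning():
    rng = np.random.default_rng(0)
    tiny = DomainDataset(values=rng.normal(size=(4, 3)), labels=np.zeros(4, dtype=int), domain_id=0)
    other = DomainDataset(
        values=rng.normal(size=(40, 3)), labels=rng.integers(0, 2, size=40), domain_id=1
    )
    target = DomainDataset(values=rng.normal(size=(40, 3)), labels=None)
    config = TrainConfig(n_iterations=1, batch_size=8, feature_dim=4, hidden_dim=8, seed=0)
    bundle = ModelBundle.build(n_domains=2, n_classes=2, input_dim=3, feature_dim=4,
                               hidden_dim=8, seed=0)
    with pytest.warns(UserWarning, match="replacement"):
        fit(bundle, [tiny, other], target, config)


def test_convergence_tolerance_stops_early(small_scenario):
    sources, target, _ = small_scenario
    config = TrainConfig(
        n_iterations=500, seed=2, feature_dim=8, hidden_dim=16, batch_size=8,
        convergence_tol=0.5,  # loose on purpose: must stop before the cap
    )
    bundle = build_bundle(small_scenario, config)
    _, log, _, _ = fit(bundle, sources, target, config)
    assert len(log) < 500


# --- inference -----------------------------------------------------------

class StubClassifier:
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def __call__(self, feats):
        n = feats.data.shape[0] if isinstance(feats, Tensor) else feats.shape[0]
        return Tensor(np.tile(self.probs, (n, 1)))

    def parameters(self):
        return []


def stub_bundle(weights_probs, n_classes=2):
    bundle = ModelBundle.build(
        n_domains=len(weights_probs), n_classes=n_classes, input_dim=3,
        feature_dim=4, hidden_dim=8, seed=0,
    )
    bundle.classifiers = [StubClassifier(p) for p in weights_probs]
    bundle.fitted = True
    return bundle


def test_degenerate_weight_recovers_single_classifier():
    bundle = stub_bundle([[0.9, 0.1], [0.2, 0.8]])
    weights = WeightState(w=np.array([1.0, 0.0]), raw=np.ones(2), distances=np.zeros(2))
    labels, scores = predict_target(bundle, np.zeros((3, 3)), weights, mode="weights")
    assert np.allclose(scores, [0.9, 0.1])
    assert np.all(labels == 0)


def test_equal_weight_ensemble_hand_example():
    bundle = stub_bundle([[0.9, 0.1], [0.2, 0.8]])
    weights = WeightState(w=np.array([0.5, 0.5]), raw=np.ones(2), distances=np.zeros(2))
    labels, scores = predict_target(bundle, np.zeros((1, 3)), weights, mode="weights")
    assert np.allclose(scores, [[0.55, 0.45]])
    assert labels[0] == 0  # argmax, ties broken toward the lowest index


def test_ensemble_scores_are_convex_combinations(rng):
    probs = [rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))]
    bundle = stub_bundle(probs, n_classes=3)
    w = rng.random(2)
    w /= w.sum()
    weights = WeightState(w=w, raw=np.ones(2), distances=np.zeros(2))
    _, scores = predict_target(bundle, np.zeros((4, 3)), weights, mode="weights")
    lower = np.minimum(probs[0], probs[1])
    upper = np.maximum(probs[0], probs[1])
    assert np.all(scores >= lower - 1e-12) and np.all(scores <= upper + 1e-12)


def test_predicting_before_fit_raises():
    bundle = ModelBundle.build(n_domains=1, n_classes=2, input_dim=3, feature_dim=4,
                               hidden_dim=8, seed=0)
    weights = WeightState(w=np.array([1.0]), raw=np.ones(1), distances=np.zeros(1))
    with pytest.raises(NotFittedError):
        predict_target(bundle, np.zeros((2, 3)), weights)


# --- image path ----------------------------------------------------------

def test_image_training_smoke_preserves_log_identity():
    from camsda.synthetic import DomainShift, ScenarioSpec, generate_image_scenario

    spec = ScenarioSpec(
        n_domains=2, n_classes=2, shared_classes=(0, 1), private_classes={},
        samples_per_class=8, image_size=32,
        domain_shift=(DomainShift(), DomainShift(translation=(0.1,))),
        noise_sd=0.05, seed=1,
    )
    sources, target, _ = generate_image_scenario(spec)
    config = TrainConfig(n_iterations=3, batch_size=4, feature_dim=8, seed=0)
    bundle = ModelBundle.build(n_domains=2, n_classes=2, input_kind="images",
                               feature_dim=8, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny domains sample with replacement
        bundle, log, weights, relevance = fit(bundle, sources, target, config)
    for r in log:
        assert r.l_total == pytest.approx(r.l_class + r.l_awmd + r.l_cls, rel=1e-9)
    labels, scores = predict_target(bundle, target.values[:4], weights, relevance)
    assert labels.shape == (4,) and scores.shape == (4, 2)
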