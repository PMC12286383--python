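"""Training loop: loss assembly, SGD updates, convergence, inference.

Each iteration samples a mini-batch of ``m`` labeled samples from every
source domain plus ``m`` unlabeled target samples, pushes everything
through the shared extractor, and assembles

    L_total = L_class + L_awmd + L_cls

where ``L_class`` is the joint-label cross-entropy of the class-aware
head, ``L_awmd`` the reweighted moment-alignment loss, and ``L_cls`` the
sum over domains of each per-domain classifier's cross-entropy on its
own labeled batch.  The adaptive contribution weights are recomputed
every iteration from the *unweighted* source-to-target moment distances
of the current batch and held constant inside the weighted losses, which
breaks the circular definition of weight and distance.  One SGD step
(momentum 0.9, weight decay 5e-4, lr 1e-3 by default) updates all
parameters jointly.

Target inference ensembles the per-domain classifiers:
``score(x) = sum_i w_hat_i C_i(M(x))`` with ``w_hat`` the renormalised
element-wise product of the moment-based weights ``w`` and the class
relevance vector ``w^c`` (pure-``w`` and pure-``w^c`` modes by config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor
from .class_aware import RelevanceVector, class_aware_loss, target_relevance
from .moments import alignment_loss, compute_moments, pair_distance
from .networks import SGD, ModelBundle
from .synthetic import DomainDataset
from .weighting import WeightState, contribution_weights, update_weight_schedule

__all__ = [
    "TrainConfig",
    "TrainLogRecord",
    "TrainingDivergenceError",
    "NotFittedError",
    "classification_loss",
    "total_loss",
    "train_step",
    "fit",
    "predict_target",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


class NotFittedError(RuntimeError):
    """Raised when inference is requested before fitting."""


@dataclass
class TrainConfig:
    """Hyper-parameters of the adaptation run.

    Defaults follow the published protocol: SGD with learning rate
    0.001, momentum 0.9 and weight decay 0.0005.  ``st_mode`` selects the
    source/target alignment reading ("simplified" or "paper-literal");
    the two ``use_*`` switches are the ablation controls;
    ``weight_momentum`` optionally smooths the adaptive-weight distances
    across iterations (0 = recompute fresh every iteration).
    """

    n_iterations: int = 2000
    batch_size: int = 32
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    seed: int = 0
    st_mode: str = "simplified"
    use_class_aware: bool = True
    use_reweighting: bool = True
    convergence_tol: Optional[float] = None
    weight_momentum: float = 0.9
    ensemble_mode: str = "sample"  # sample | product | weights | relevance
    coef_class: float = 1.0
    coef_awmd: float = 1.0
    coef_cls: float = 1.0
    feature_dim: int = 32
    hidden_dim: int = 128

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2 (second moments need spread)")
        if self.st_mode not in ("simplified", "paper-literal"):
            raise ValueError(f"unknown st_mode {self.st_mode!r}")
        if self.ensemble_mode not in ("sample", "product", "weights", "relevance"):
            raise ValueError(f"unknown ensemble_mode {self.ensemble_mode!r}")
        if not (0.0 <= self.weight_momentum <= 1.0):
            raise ValueError("weight_momentum must lie in [0, 1]")


@dataclass
class TrainLogRecord:
    """One iteration's loss breakdown and adaptive weights.

    The logged terms are the effective (coefficient-scaled)
    contributions, so ``l_total = l_class + l_awmd + l_cls`` holds at
    every iteration, ablations included.
    """

    iteration: int
    l_class: float
    l_ss: float
    l_st: float
    l_awmd: float
    l_cls: float
    l_total: float
    weights: np.ndarray

    def header(self) -> List[str]:
        return ["iteration", "l_class", "l_ss", "l_st", "l_awmd", "l_cls", "l_total"] + [
            f"w_{i + 1}" for i in range(len(self.weights))
        ]

    def row(self) -> List[float]:
        return [
            self.iteration,
            self.l_class,
            self.l_ss,
            self.l_st,
            self.l_awmd,
            self.l_cls,
            self.l_total,
        ] + list(self.weights)


def classification_loss(classifier_probs: Sequence, class_labels: Sequence):
    """Sum over domains of each classifier's mean cross-entropy.

    Note the outer SUM (not mean) over domains: every domain classifier
    contributes its full average loss.
    """
    if len(classifier_probs) != len(class_labels):
        raise ValueError("need one label list per domain")
    loss = None
    for probs, labels in zip(classifier_probs, class_labels):
        term = class_aware_loss(probs, labels)  # same cross-entropy form
        loss = term if loss is None else loss + term
    if loss is None:
        raise ValueError("need at least one domain")
    return loss


def total_loss(l_class, l_awmd, l_cls, coefficients: Tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Composite objective; unweighted sum of the three terms by default."""
    parts = [float(l_class), float(l_awmd), float(l_cls)]
    if not all(np.isfinite(parts)):
        raise TrainingDivergenceError(f"non-finite loss components {parts}")
    a, b, c = coefficients
    return a * l_class + b * l_awmd + c * l_cls


def _batch_weight_state(
    source_features: Sequence[Tensor],
    target_features: Tensor,
    config: TrainConfig,
    previous: Optional[WeightState],
) -> WeightState:
    """Adaptive weights from the current batch's unweighted distances."""
    n = len(source_features)
    if not config.use_reweighting:
        return WeightState.uniform(n)
    t_moments = compute_moments(target_features.data)
    distances = np.array(
        [pair_distance(compute_moments(f.data), t_moments) for f in source_features]
    )
    if previous is not None and config.weight_momentum > 0.0:
        return update_weight_schedule(previous, distances, config.weight_momentum)
    return contribution_weights(distances)


def train_step(
    bundle: ModelBundle,
    source_batches: Sequence[Tuple[np.ndarray, np.ndarray]],
    target_batch: np.ndarray,
    config: TrainConfig,
    optimizer: Optional[SGD] = None,
    previous_weights: Optional[WeightState] = None,
    iteration: int = 0,
) -> Tuple[TrainLogRecord, WeightState]:
    """One full iteration: losses, adaptive weights, one SGD update."""
    n = len(source_batches)
    m = source_batches[0][0].shape[0]
    for values, labels in source_batches:
        if values.shape[0] != m or labels.shape[0] != m:
            raise ValueError("every source batch must hold m labeled samples")
    if optimizer is None:
        optimizer = SGD(
            bundle.parameters(),
            lr=config.learning_rate,
            momentum=config.momentum,
            weight_decay=config.weight_decay,
        )

    source_features = [bundle.features(values) for values, _ in source_batches]
    target_features = bundle.features(target_batch)
    q = bundle.label_map.n_classes

    # class-aware joint-label loss over all source samples
    if config.use_class_aware:
        counts = np.array([f.data.shape[0] for f in source_features], dtype=np.float64)
        share = counts / counts.sum()
        l_class_t = None
        for i, features in enumerate(source_features):
            joint = i * q + np.asarray(source_batches[i][1], dtype=np.intp)
            term = class_aware_loss(bundle.class_aware_head(features), joint) * share[i]
            l_class_t = term if l_class_t is None else l_class_t + term
    else:
        l_class_t = None

    weight_state = _batch_weight_state(source_features, target_features, config, previous_weights)

    breakdown = alignment_loss(
        source_features,
        target_features,
        weight_state,
        mode=config.st_mode,
        allow_single=(n == 1),
    )

    l_cls_t = classification_loss(
        [clf(f) for clf, f in zip(bundle.classifiers, source_features)],
        [labels for _, labels in source_batches],
    )

    terms = []
    if l_class_t is not None and config.coef_class != 0.0:
        terms.append(l_class_t * config.coef_class)
    if config.coef_awmd != 0.0 and isinstance(breakdown.total, Tensor):
        terms.append(breakdown.total * config.coef_awmd)
    if config.coef_cls != 0.0:
        terms.append(l_cls_t * config.coef_cls)
    if not terms:
        raise ValueError("all loss terms are disabled; nothing to optimise")
    objective = terms[0]
    for t in terms[1:]:
        objective = objective + t

    if not np.isfinite(float(objective)):
        raise TrainingDivergenceError(f"non-finite total loss at iteration {iteration}")

    optimizer.zero_grad()
    objective.backward()
    optimizer.step()

    l_class = config.coef_class * float(l_class_t) if l_class_t is not None else 0.0
    l_ss = config.coef_awmd * float(breakdown.ss_loss)
    l_st = config.coef_awmd * float(breakdown.st_loss)
    l_awmd = l_ss + l_st
    l_cls = config.coef_cls * float(l_cls_t)
    record = TrainLogRecord(
        iteration=iteration,
        l_class=l_class,
        l_ss=l_ss,
        l_st=l_st,
        l_awmd=l_awmd,
        l_cls=l_cls,
        l_total=l_class + l_awmd + l_cls,
        weights=weight_state.w.copy(),
    )
    return record, weight_state


def _augment_images(batch: np.ndarray, rng: np.random.Generator, pad: int = 4) -> np.ndarray:
    """Random crop after reflect padding, plus horizontal flip with p=0.5."""
    n, h, w = batch.shape
    padded = np.pad(batch, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")
    out = np.empty_like(batch)
    offsets = rng.integers(0, 2 * pad + 1, size=(n, 2))
    flips = rng.random(n) < 0.5
    for k in range(n):
        dy, dx = offsets[k]
        crop = padded[k, dy : dy + h, dx : dx + w]
        out[k] = crop[:, ::-1] if flips[k] else crop
    return out


def _sample_batch(
    dataset: DomainDataset, m: int, rng: np.random.Generator, augment: bool
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    replace = len(dataset) < m
    idx = rng.choice(len(dataset), size=m, replace=replace)
    values = dataset.values[idx]
    if augment and values.ndim == 3:
        values = _augment_images(values, rng)
    labels = dataset.labels[idx] if dataset.labels is not None else None
    return values, labels


def fit(
    bundle: ModelBundle,
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: TrainConfig,
) -> Tuple[ModelBundle, List[TrainLogRecord], WeightState, Optional[RelevanceVector]]:
    """Run the full adaptation loop and compute the final inference weights."""
    if not sources:
        raise ValueError("need at least one source domain")
    if target.labels is not None:
        raise ValueError("the target dataset must be unlabeled; keep truth in metadata")
    rng = np.random.default_rng(config.seed)
    m = config.batch_size
    for d in sources:
        if len(d) < m:
            warnings.warn(
                f"domain {d.domain_id} has {len(d)} < {m} samples; sampling with replacement",
                stacklevel=2,
            )
    if len(target) < m:
        warnings.warn("target smaller than batch size; sampling with replacement", stacklevel=2)

    optimizer = SGD(
        bundle.parameters(),
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    augment = sources[0].values.ndim == 3

    log: List[TrainLogRecord] = []
    weight_state: Optional[WeightState] = None
    window = 50
    for k in range(config.n_iterations):
        source_batches = [_sample_batch(d, m, rng, augment) for d in sources]
        target_values, _ = _sample_batch(target, m, rng, augment)
        record, weight_state = train_step(
            bundle,
            source_batches,
            target_values,
            config,
            optimizer=optimizer,
            previous_weights=weight_state,
            iteration=k,
        )
        log.append(record)
        if config.convergence_tol is not None and len(log) >= 2 * window:
            recent = np.mean([r.l_total for r in log[-window:]])
            prior = np.mean([r.l_total for r in log[-2 * window : -window]])
            if abs(recent - prior) / max(abs(prior), 1e-12) < config.convergence_tol:
                break

    bundle.fitted = True
    final_weights, relevance = finalize_weights(bundle, sources, target, config)
    return bundle, log, final_weights, relevance


def finalize_weights(
    bundle: ModelBundle,
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: TrainConfig,
    chunk: int = 512,
) -> Tuple[WeightState, Optional[RelevanceVector]]:
    """Full-dataset adaptive weights and class relevance after training."""
    target_feats = _features_in_chunks(bundle, target.values, chunk)
    if config.use_reweighting:
        t_moments = compute_moments(target_feats)
        distances = np.array(
            [
                pair_distance(
                    compute_moments(_features_in_chunks(bundle, d.values, chunk)), t_moments
                )
                for d in sources
            ]
        )
        weight_state = contribution_weights(distances)
    else:
        weight_state = WeightState.uniform(len(sources))
    relevance = None
    if config.use_class_aware:
        probs = _head_probs_in_chunks(bundle, target_feats, chunk)
        relevance = target_relevance(probs, bundle.label_map)
    return weight_state, relevance


def _features_in_chunks(bundle: ModelBundle, values: np.ndarray, chunk: int) -> np.ndarray:
    parts = [
        bundle.features(values[i : i + chunk]).data for i in range(0, values.shape[0], chunk)
    ]
    return np.vstack(parts)


def _head_probs_in_chunks(bundle: ModelBundle, feats: np.ndarray, chunk: int) -> np.ndarray:
    parts = [
        bundle.class_aware_head(Tensor(feats[i : i + chunk])).data
        for i in range(0, feats.shape[0], chunk)
    ]
    return np.vstack(parts)


def ensemble_weights(
    weights: WeightState,
    relevance: Optional[RelevanceVector],
    mode: str = "product",
) -> np.ndarray:
    """Combine moment weights and class relevance into one global mixture.

    For the per-sample "sample" mode this returns the batch-level view
    (the product blend); the actual routing happens in
    :func:`predict_target`.
    """
    w = weights.w
    if mode == "weights" or relevance is None:
        return w / w.sum()
    wc = relevance.wc
    if mode == "relevance":
        return wc / wc.sum()
    if mode in ("product", "sample"):
        combined = w * wc
        if combined.sum() <= 0:
            return w / w.sum()
        return combined / combined.sum()
    raise ValueError(f"unknown ensemble mode {mode!r}")


def predict_target(
    bundle: ModelBundle,
    samples: np.ndarray,
    weights: WeightState,
    relevance: Optional[RelevanceVector] = None,
    mode: str = "sample",
    chunk: int = 512,
) -> Tuple[np.ndarray, np.ndarray]:
    """Weighted classifier-ensemble prediction for target samples.

    The default "sample" mode routes each sample individually: the
    class-aware head's per-domain probability mass on that sample,
    multiplied by the moment-based weights ``w`` and renormalised, sets
    the classifier mixture — so a sample that the head attributes to one
    source's private classes is scored by that source's classifier.  The
    global modes ("product", "weights", "relevance") use one mixture for
    all samples.  Returns (labels, scores); ties go to the lowest class
    index.
    """
    if not bundle.fitted:
        raise NotFittedError("the model bundle has not been fitted")
    feats = _features_in_chunks(bundle, np.asarray(samples, dtype=np.float64), chunk)
    n_dom = bundle.label_map.n_domains
    q = bundle.label_map.n_classes
    if mode == "sample" and relevance is None:
        mode = "weights"  # no class-aware head trained; fall back to w alone
    if mode == "sample":
        head_probs = _head_probs_in_chunks(bundle, feats, chunk)
        mass = head_probs.reshape(feats.shape[0], n_dom, q).sum(axis=2)
        w_hat = mass * weights.w[None, :]
        w_hat /= w_hat.sum(axis=1, keepdims=True)
    else:
        w_hat = np.broadcast_to(ensemble_weights(weights, relevance, mode), (feats.shape[0], n_dom))
    scores = np.zeros((feats.shape[0], q))
    for i, clf in enumerate(bundle.classifiers):
        scores += w_hat[:, i : i + 1] * clf(Tensor(feats)).data
    return scores.argmax(axis=1), scores
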