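"""Class-aware relabeling over joint (domain, class) labels.

Under class shift the same class label may mean differently distributed
data in different source domains, so the class-aware head treats each
(domain, class) combination as its own category: with N source domains
and Q classes in the union label space, source samples are relabeled
onto N*Q joint labels and the head is trained with cross-entropy on
them.  Applied to unlabeled target samples, the head's probabilities are
marginalised over each domain's block of joint labels to give the class
relevance vector ``w^c`` — how much target mass each source domain's
categories attract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .autodiff import Tensor

__all__ = [
    "JointLabelMap",
    "RelevanceVector",
    "relabel_sources",
    "class_aware_loss",
    "target_relevance",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class JointLabelMap:
    """Row-major bijection (domain i, class c) <-> joint index i*Q + c."""

    n_domains: int
    n_classes: int

    def __post_init__(self):
        if self.n_domains < 1 or self.n_classes < 1:
            raise ValueError("need at least one domain and one class")

    @property
    def n_joint(self) -> int:
        return self.n_domains * self.n_classes

    def forward(self, domain: int, cls: int) -> int:
        if not (0 <= domain < self.n_domains):
            raise ValueError(f"domain index {domain} out of range [0, {self.n_domains})")
        if not (0 <= cls < self.n_classes):
            raise ValueError(f"class label {cls} out of range [0, {self.n_classes})")
        return domain * self.n_classes + cls

    def backward(self, joint: int) -> Tuple[int, int]:
        if not (0 <= joint < self.n_joint):
            raise ValueError(f"joint label {joint} out of range [0, {self.n_joint})")
        return divmod(joint, self.n_classes)

    def domain_block(self, domain: int) -> slice:
        """Column slice of the joint axis owned by one domain."""
        if not (0 <= domain < self.n_domains):
            raise ValueError(f"domain index {domain} out of range [0, {self.n_domains})")
        return slice(domain * self.n_classes, (domain + 1) * self.n_classes)

    # joint maps travel next to checkpoints as a small JSON sidecar
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_domains": self.n_domains,
                "n_classes": self.n_classes,
                "encoding": "row-major",
            }
        )

    @classmethod
    def from_json(cls, text: Union[str, Path]) -> "JointLabelMap":
        payload = json.loads(text)
        if payload.get("encoding", "row-major") != "row-major":
            raise ValueError("unsupported joint-label encoding")
        return cls(n_domains=int(payload["n_domains"]), n_classes=int(payload["n_classes"]))


def relabel_sources(
    labels: Sequence[Sequence[int]], label_map: JointLabelMap
) -> List[np.ndarray]:
    """Map per-domain class labels onto joint (domain, class) labels."""
    if len(labels) > label_map.n_domains:
        raise ValueError("more label lists than domains in the map")
    joint = []
    for domain, domain_labels in enumerate(labels):
        arr = np.asarray(domain_labels, dtype=np.intp)
        if arr.size and (arr.min() < 0 or arr.max() >= label_map.n_classes):
            raise ValueError(f"domain {domain} has class labels outside [0, {label_map.n_classes})")
        joint.append(domain * label_map.n_classes + arr)
    return joint


def _check_rows(probs: np.ndarray) -> None:
    if not np.all(np.isfinite(probs)):
        raise ValueError("probabilities contain non-finite entries")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")


def class_aware_loss(predicted_probs, joint_labels):
    """Mean negative log-probability of the true joint label.

    Accepts a plain probability matrix (returns a float) or a
    :class:`~camsda.autodiff.Tensor` on the training tape (returns a
    Tensor).  Probabilities are floored at 1e-12 before the log.
    """
    labels = np.asarray(joint_labels, dtype=np.intp)
    is_tensor = isinstance(predicted_probs, Tensor)
    raw = predicted_probs.data if is_tensor else np.asarray(predicted_probs, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] == 0:
        raise ValueError("need a non-empty samples x joint-labels probability matrix")
    if labels.shape[0] != raw.shape[0]:
        raise ValueError("one joint label per sample is required")
    if labels.size and (labels.min() < 0 or labels.max() >= raw.shape[1]):
        raise ValueError("joint label outside the probability matrix width")
    _check_rows(raw)
    if is_tensor:
        picked = predicted_probs.gather_rows(labels).clip_min(PROB_FLOOR)
        return -picked.log().mean()
    picked = np.maximum(raw[np.arange(raw.shape[0]), labels], PROB_FLOOR)
    return float(-np.log(picked).mean())


@dataclass
class RelevanceVector:
    """Class relevance vector w^c: per-domain target mass, summing to 1."""

    wc: np.ndarray

    def __post_init__(self):
        self.wc = np.asarray(self.wc, dtype=np.float64)
        if np.any(self.wc < 0) or not np.isclose(self.wc.sum(), 1.0, atol=1e-9):
            raise ValueError("relevance vector must be non-negative and sum to 1")

    def __len__(self) -> int:
        return self.wc.shape[0]


def target_relevance(predicted_probs, label_map: JointLabelMap) -> RelevanceVector:
    """Marginalise joint probabilities into the per-domain relevance w^c.

    Each domain's block of joint-label columns is summed per sample,
    averaged over the target batch, and the per-domain masses are
    renormalised.
    """
    probs = predicted_probs.data if isinstance(predicted_probs, Tensor) else np.asarray(
        predicted_probs, dtype=np.float64
    )
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("need a non-empty target probability matrix")
    if probs.shape[1] != label_map.n_joint:
        raise ValueError("probability width must be n_domains * n_classes")
    _check_rows(probs)
    mass = np.array(
        [probs[:, label_map.domain_block(i)].sum(axis=1).mean() for i in range(label_map.n_domains)]
    )
    return RelevanceVector(wc=mass / mass.sum())
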