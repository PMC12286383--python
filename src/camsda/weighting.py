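"""Adaptive per-source contribution weights.

A source that already sits close to the target (small unweighted moment
distance) should dominate the alignment and the classifier ensemble, so
each source's raw weight is the inverse of its moment distance to the
target, and the N raw weights are normalised to sum to 1:

    w_a^i = 1 / (d_i + eps),     w_i = w_a^i / sum_j w_a^j

The epsilon guard (1e-8) keeps an exact distribution match at the
maximal, not undefined, weight.  Weights are recomputed from the current
mini-batch each iteration and treated as constants inside the weighted
losses (no gradient flows through them); an optional momentum smooths
the underlying distances across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightState", "contribution_weights", "update_weight_schedule", "EPSILON"]

EPSILON = 1e-8


@dataclass
class WeightState:
    """Adaptive weights ``w``, raw inverses ``raw``, and the distances behind them."""

    w: np.ndarray
    raw: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if not (self.w.shape == self.raw.shape == self.distances.shape):
            raise ValueError("w, raw and distances must share one length")
        if np.any(self.w < 0) or not np.isclose(self.w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")

    def __len__(self) -> int:
        return self.w.shape[0]

    @classmethod
    def uniform(cls, n: int) -> "WeightState":
        """Equal weights, as used when adaptive reweighting is disabled."""
        return cls(w=np.full(n, 1.0 / n), raw=np.full(n, 1.0 / n), distances=np.zeros(n))


def contribution_weights(distances) -> WeightState:
    """Normalised inverse-distance weights from source-to-target distances."""
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("need a 1-D vector of at least one distance")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and non-negative")
    raw = 1.0 / (d + EPSILON)
    return WeightState(w=raw / raw.sum(), raw=raw, distances=d)


def update_weight_schedule(state: WeightState, new_distances, momentum: float) -> WeightState:
    """Exponentially smooth the distances, then recompute the weights.

    ``momentum`` in [0, 1]: 0 reproduces the per-batch weights exactly,
    1 freezes the previous state's distances.
    """
    if not (0.0 <= momentum <= 1.0):
        raise ValueError("momentum must lie in [0, 1]")
    new = np.asarray(new_distances, dtype=np.float64)
    if new.shape != state.distances.shape:
        raise ValueError("distance vector length changed between iterations")
    smoothed = momentum * state.distances + (1.0 - momentum) * new
    return contribution_weights(smoothed)
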