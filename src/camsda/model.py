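"""Model/Results facade over the adaptation machinery.

``CamsdaModel`` is constructed from N labeled source datasets and one
unlabeled target dataset; ``fit()`` runs the full training loop and
returns a ``CamsdaResults`` holding the trained networks, the
per-iteration loss log, the final adaptive weights and class relevance,
plus prediction, scoring and summary helpers — the usual estimator
workflow:

    model = CamsdaModel(sources, target, config=TrainConfig(seed=1))
    res = model.fit()
    labels, scores = res.predict()
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import training
from .class_aware import RelevanceVector
from .networks import ModelBundle, Module
from .reporting import per_class_accuracy
from .synthetic import DomainDataset
from .training import TrainConfig, TrainLogRecord, predict_target
from .weighting import WeightState

__all__ = ["CamsdaModel", "CamsdaResults"]


class CamsdaModel:
    """Class-aware multi-source domain adaptation estimator.

    Parameters
    ----------
    sources : sequence of DomainDataset
        Labeled source domains; labels must cover ``[0, Q)`` jointly.
    target : DomainDataset
        Unlabeled target domain of the same modality.
    config : TrainConfig, optional
        Training hyper-parameters (defaults follow the published protocol).
    n_classes : int, optional
        Size of the union label space; inferred from the source labels
        when omitted.
    extractor : optional backbone override
        Any callable with ``output_dim`` and ``parameters()``.
    """

    def __init__(
        self,
        sources: Sequence[DomainDataset],
        target: DomainDataset,
        config: Optional[TrainConfig] = None,
        n_classes: Optional[int] = None,
        extractor: Optional[Module] = None,
    ):
        if not sources:
            raise ValueError("need at least one source domain")
        for d in sources:
            if d.labels is None:
                raise ValueError("source domains must be labeled")
        if target.labels is not None:
            raise ValueError("the target domain must be unlabeled")
        self.sources = list(sources)
        self.target = target
        self.config = config if config is not None else TrainConfig()
        self.n_domains = len(self.sources)
        inferred = 1 + max(int(d.labels.max()) for d in self.sources)
        self.n_classes = n_classes if n_classes is not None else inferred
        if inferred > self.n_classes:
            raise ValueError("source labels exceed the declared number of classes")
        self.input_kind = "images" if self.sources[0].values.ndim == 3 else "features"
        self.input_dim = (
            self.sources[0].values.shape[1] if self.input_kind == "features" else None
        )
        self._extractor = extractor

    @classmethod
    def from_scenario(
        cls,
        scenario: Tuple[List[DomainDataset], DomainDataset, dict],
        config: Optional[TrainConfig] = None,
        **kwargs,
    ) -> "CamsdaModel":
        """Build directly from a synthetic-scenario tuple."""
        sources, target, _ = scenario
        return cls(sources, target, config=config, **kwargs)

    def build_bundle(self) -> ModelBundle:
        return ModelBundle.build(
            n_domains=self.n_domains,
            n_classes=self.n_classes,
            input_dim=self.input_dim,
            input_kind=self.input_kind,
            feature_dim=self.config.feature_dim,
            hidden_dim=self.config.hidden_dim,
            seed=self.config.seed,
            extractor=self._extractor,
        )

    def fit(self) -> "CamsdaResults":
        """Run the adaptation loop and return the fitted results."""
        bundle = self.build_bundle()
        bundle, log, weights, relevance = training.fit(
            bundle, self.sources, self.target, self.config
        )
        return CamsdaResults(self, bundle, log, weights, relevance)

    @property
    def architecture(self) -> dict:
        return {
            "input_kind": self.input_kind,
            "input_dim": self.input_dim,
            "feature_dim": self.config.feature_dim,
            "hidden_dim": self.config.hidden_dim,
        }


class CamsdaResults:
    """Fitted adaptation run: trained networks, log, weights, predictions."""

    def __init__(
        self,
        model: CamsdaModel,
        bundle: ModelBundle,
        log_records: List[TrainLogRecord],
        weights: WeightState,
        relevance: Optional[RelevanceVector],
    ):
        self.model = model
        self.bundle = bundle
        self.log_records = log_records
        self.weights = weights
        self.relevance = relevance

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    @property
    def log(self) -> pd.DataFrame:
        """Per-iteration loss breakdown and adaptive weights."""
        if not self.log_records:
            return pd.DataFrame()
        header = self.log_records[0].header()
        return pd.DataFrame([r.row() for r in self.log_records], columns=header)

    @property
    def ensemble_weights(self) -> np.ndarray:
        return training.ensemble_weights(self.weights, self.relevance, self.config.ensemble_mode)

    def predict(
        self, samples: Optional[np.ndarray] = None, mode: Optional[str] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Ensemble labels and class scores (defaults to the target data)."""
        if samples is None:
            samples = self.model.target.values
        return predict_target(
            self.bundle,
            samples,
            self.weights,
            self.relevance,
            mode=mode if mode is not None else self.config.ensemble_mode,
        )

    def accuracy(self, true_labels: Sequence[int], samples: Optional[np.ndarray] = None) -> float:
        labels, _ = self.predict(samples)
        true = np.asarray(true_labels, dtype=np.intp)
        return float((labels == true).mean())

    def per_class_accuracy(
        self, true_labels: Sequence[int], samples: Optional[np.ndarray] = None
    ) -> np.ndarray:
        labels, _ = self.predict(samples)
        return per_class_accuracy(true_labels, labels, self.model.n_classes)

    def write_log_csv(self, path) -> None:
        self.log.to_csv(path, index=False)

    def save(self, path) -> None:
        """Checkpoint (.npz parameters + .json sidecar)."""
        from .io import save_checkpoint

        save_checkpoint(
            path, self.bundle, self.config, self.weights, self.relevance, self.model.architecture
        )

    def plot_losses(self, path=None):
        """Loss-curve figure; returns the matplotlib Axes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        frame = self.log
        fig, ax = plt.subplots(figsize=(7, 4))
        for col in ("l_class", "l_awmd", "l_cls", "l_total"):
            ax.plot(frame["iteration"], frame[col], label=col)
        ax.set_xlabel("iteration")
        ax.set_ylabel("loss")
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax

    def summary(self) -> str:
        """Human-readable account of the fitted run."""
        cfg = dataclasses.asdict(self.config)
        frame = self.log
        lines = [
            "Class-aware multi-source domain adaptation (reweighted moment matching)",
            "=" * 72,
            f"domains: {self.model.n_domains} sources -> 1 target"
            f" | classes: {self.model.n_classes} | input: {self.model.input_kind}",
            f"iterations run: {len(self.log_records)} (configured {cfg['n_iterations']})"
            f" | batch size: {cfg['batch_size']} | seed: {cfg['seed']}",
            f"optimizer: SGD lr={cfg['learning_rate']} momentum={cfg['momentum']}"
            f" weight_decay={cfg['weight_decay']}",
            f"strategies: class_aware={cfg['use_class_aware']}"
            f" reweighting={cfg['use_reweighting']} st_mode={cfg['st_mode']}",
            "-" * 72,
        ]
        if len(frame):
            last = frame.iloc[-1]
            lines.append(
                "final losses: "
                f"l_class={last['l_class']:.4f} l_awmd={last['l_awmd']:.4f} "
                f"l_cls={last['l_cls']:.4f} l_total={last['l_total']:.4f}"
            )
        lines.append(
            "adaptive weights w:      "
            + " ".join(f"{v:.4f}" for v in self.weights.w)
        )
        if self.relevance is not None:
            lines.append(
                "class relevance w^c:     " + " ".join(f"{v:.4f}" for v in self.relevance.wc)
            )
        lines.append(
            "ensemble weights w_hat:  " + " ".join(f"{v:.4f}" for v in self.ensemble_weights)
        )
        return "\n".join(lines)
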