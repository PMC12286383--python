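"""Run configuration, dataset loading, and checkpoint serialization.

Feature-mode domains are CSV (feature columns plus a ``label`` column,
``label = -1`` marking the unlabeled target) or NPY files; image-mode
domains are directories of PNG/JPEG files grouped into class subfolders
and resized to 128 x 128 grayscale on load.  Checkpoints are a single
``.npz`` of parameter arrays with a JSON sidecar recording the
architecture, the joint label map, a hash of the run configuration and
the final adaptive weights, which is enough to rebuild the bundle for
inference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .class_aware import JointLabelMap, RelevanceVector
from .moments import TARGET
from .networks import ModelBundle
from .synthetic import DomainDataset, DomainShift, ScenarioSpec
from .training import TrainConfig
from .weighting import WeightState

__all__ = [
    "RunConfig",
    "load_run_config",
    "load_feature_domain",
    "load_image_domain",
    "save_checkpoint",
    "load_checkpoint",
    "scenario_spec_from_yaml",
    "write_scenario",
]

IMAGE_SIDE = 128

_TRAIN_KEYS = {
    "n_iterations",
    "batch_size",
    "learning_rate",
    "momentum",
    "weight_decay",
    "seed",
    "st_mode",
    "convergence_tol",
    "weight_momentum",
}
_ABLATION_KEYS = {
    "use_class_aware",
    "use_reweighting",
    "ensemble_mode",
    "coef_class",
    "coef_awmd",
    "coef_cls",
}
_MODEL_KEYS = {"feature_dim", "hidden_dim"}
_DATA_KEYS = {"kind", "sources", "target"}


@dataclasses.dataclass
class RunConfig:
    """Parsed train-command configuration: data paths plus TrainConfig."""

    kind: str
    sources: List[str]
    target: str
    train: TrainConfig


def _reject_unknown(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} config block: {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError("run config must be a YAML mapping")
    _reject_unknown(payload, {"data", "model", "train", "ablation"}, "top-level")
    data = payload.get("data", {})
    _reject_unknown(data, _DATA_KEYS, "data")
    model = payload.get("model", {})
    _reject_unknown(model, _MODEL_KEYS, "model")
    train = payload.get("train", {})
    _reject_unknown(train, _TRAIN_KEYS, "train")
    ablation = payload.get("ablation", {})
    _reject_unknown(ablation, _ABLATION_KEYS, "ablation")
    config = TrainConfig(**train, **ablation, **model)
    kind = data.get("kind", "features")
    if kind not in ("features", "images"):
        raise ValueError(f"unknown data kind {kind!r}")
    return RunConfig(
        kind=kind,
        sources=[str(p) for p in data.get("sources", [])],
        target=str(data.get("target", "")),
        train=config,
    )


def config_hash(config: TrainConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --- feature / image domain loading ----------------------------------

def load_feature_domain(path, domain_id: int = TARGET) -> DomainDataset:
    """CSV with a ``label`` column (or NPY, last column = label); -1 = unlabeled."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        raw = np.load(path)
        values, labels = raw[:, :-1], raw[:, -1].astype(np.intp)
    else:
        import pandas as pd

        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError(f"{path} has no 'label' column")
        labels = frame.pop("label").to_numpy(dtype=np.intp)
        values = frame.to_numpy(dtype=np.float64)
    if np.all(labels < 0):
        return DomainDataset(values=values, labels=None, domain_id=domain_id)
    return DomainDataset(values=values, labels=labels, domain_id=domain_id)


def load_image_domain(
    directory, domain_id: int = TARGET, class_names: Optional[List[str]] = None
) -> Tuple[DomainDataset, List[str]]:
    """Per-class subfolders of PNG/JPEG, resized to 128 x 128 grayscale in [0, 1].

    A directory containing images directly (no subfolders) is loaded as
    an unlabeled target domain.
    """
    from PIL import Image

    directory = Path(directory)
    subdirs = sorted(d for d in directory.iterdir() if d.is_dir())

    def load_one(file: Path) -> np.ndarray:
        with Image.open(file) as img:
            gray = img.convert("L").resize((IMAGE_SIDE, IMAGE_SIDE), Image.BILINEAR)
        return np.asarray(gray, dtype=np.float64) / 255.0

    patterns = ("*.png", "*.jpg", "*.jpeg")
    if not subdirs:
        files = sorted(f for pat in patterns for f in directory.glob(pat))
        if not files:
            raise ValueError(f"no images found under {directory}")
        values = np.stack([load_one(f) for f in files])
        return DomainDataset(values=values, labels=None, domain_id=domain_id), class_names or []

    names = class_names or [d.name for d in subdirs]
    values, labels = [], []
    for d in subdirs:
        cls = names.index(d.name)
        files = sorted(f for pat in patterns for f in d.glob(pat))
        for f in files:
            values.append(load_one(f))
            labels.append(cls)
    if not values:
        raise ValueError(f"no images found under {directory}")
    return (
        DomainDataset(values=np.stack(values), labels=np.asarray(labels), domain_id=domain_id),
        names,
    )


# --- checkpoints ------------------------------------------------------

def save_checkpoint(
    path,
    bundle: ModelBundle,
    config: TrainConfig,
    weights: WeightState,
    relevance: Optional[RelevanceVector],
    architecture: Dict,
) -> None:
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(bundle.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "label_map": json.loads(bundle.label_map.to_json()),
        "architecture": architecture,
        "weights": {
            "w": weights.w.tolist(),
            "raw": weights.raw.tolist(),
            "distances": weights.distances.tolist(),
        },
        "relevance": relevance.wc.tolist() if relevance is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> Tuple[ModelBundle, TrainConfig, WeightState, Optional[RelevanceVector]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arch = sidecar["architecture"]
    label_map = JointLabelMap(
        n_domains=sidecar["label_map"]["n_domains"],
        n_classes=sidecar["label_map"]["n_classes"],
    )
    bundle = ModelBundle.build(
        n_domains=label_map.n_domains,
        n_classes=label_map.n_classes,
        input_dim=arch.get("input_dim"),
        input_kind=arch["input_kind"],
        feature_dim=arch["feature_dim"],
        hidden_dim=arch.get("hidden_dim", 64),
        seed=0,
    )
    with np.load(path.with_suffix(".npz")) as payload:
        arrays = [payload[f"param_{i}"] for i in range(len(payload.files))]
    bundle.load_state_arrays(arrays)
    bundle.fitted = True
    config = TrainConfig(**sidecar["config"])
    w = sidecar["weights"]
    weights = WeightState(
        w=np.asarray(w["w"]), raw=np.asarray(w["raw"]), distances=np.asarray(w["distances"])
    )
    relevance = (
        RelevanceVector(wc=np.asarray(sidecar["relevance"]))
        if sidecar["relevance"] is not None
        else None
    )
    return bundle, config, weights, relevance


# --- scenario specs and simulated output ------------------------------

def scenario_spec_from_yaml(path) -> Tuple[ScenarioSpec, str]:
    """Parse a scenario YAML; returns the spec and the mode (features|images)."""
    payload = yaml.safe_load(Path(path).read_text())
    allowed = {
        "mode",
        "n_domains",
        "n_classes",
        "shared_classes",
        "private_classes",
        "samples_per_class",
        "feature_dim",
        "image_size",
        "noise_sd",
        "prototype_scale",
        "seed",
        "shifts",
    }
    _reject_unknown(payload, allowed, "scenario")
    mode = payload.pop("mode", "features")
    shifts = tuple(
        DomainShift(translation=tuple(s.get("translation", ())), scale=float(s.get("scale", 1.0)))
        for s in payload.pop("shifts", [])
    )
    private = {int(k): tuple(v) for k, v in payload.pop("private_classes", {}).items()}
    spec = ScenarioSpec(
        shared_classes=tuple(payload.pop("shared_classes", ())),
        private_classes=private,
        domain_shift=shifts,
        **payload,
    )
    return spec, mode


def write_scenario(out_dir, sources: List[DomainDataset], target: DomainDataset, metadata: dict) -> None:
    """Write per-domain CSV/NPY (features) or PNG folders (images) + metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_mode = sources[0].values.ndim == 3

    def dump(dataset: DomainDataset, name: str) -> None:
        if image_mode:
            from PIL import Image

            root = out / name
            labels = dataset.labels
            for k in range(len(dataset)):
                sub = root / (f"class_{labels[k]}" if labels is not None else "unlabeled")
                sub.mkdir(parents=True, exist_ok=True)
                img = (np.clip(dataset.values[k], 0, 1) * 255).astype(np.uint8)
                Image.fromarray(img).save(sub / f"{name}_{k:05d}.png")
        else:
            import pandas as pd

            frame = pd.DataFrame(
                dataset.values, columns=[f"f{j}" for j in range(dataset.values.shape[1])]
            )
            frame["label"] = dataset.labels if dataset.labels is not None else -1
            frame.to_csv(out / f"{name}.csv", index=False)

    for i, s in enumerate(sources):
        dump(s, f"source_{i}")
    dump(target, "target")
    meta = {
        "domain_classes": {str(k): list(v) for k, v in metadata["domain_classes"].items()},
        "target_labels": metadata["target_labels"].tolist(),
        "seed": metadata["spec"].seed,
        "n_domains": metadata["spec"].n_domains,
        "n_classes": metadata["spec"].n_classes,
    }
    (out / "metadata.json").write_text(json.dumps(meta))
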