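"""Network building blocks: shared extractor, class-aware head, per-domain classifiers.

The backbone contract is deliberately small: an extractor is any object
with ``__call__(Tensor) -> Tensor``, an ``output_dim`` attribute and a
``parameters()`` method, so externally trained feature extractors (e.g.
a pretrained convolutional backbone exposing pooled features) can be
plugged in.  Two desk-scale defaults are bundled: a two-layer perceptron
for feature-vector inputs and a compact three-layer convolutional net
for grayscale images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .class_aware import JointLabelMap

__all__ = [
    "Linear",
    "MLPExtractor",
    "SmallConvExtractor",
    "SoftmaxHead",
    "ModelBundle",
    "SGD",
]


class Module:
    """Base for parameterised blocks; parameters are trainable Tensors."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLPExtractor(Module):
    """Two-layer perceptron backbone for feature-vector inputs.

    The output layer is initialised at a tenth of the He scale so that
    features start small: the moment-alignment terms then grow together
    with the discriminative structure instead of dominating the first
    updates (large mismatched initial moments can otherwise crush the
    features to zero before the classifiers shape them).
    """

    def __init__(self, input_dim: int, output_dim: int = 32, hidden_dim: int = 128,
                 rng: Optional[np.random.Generator] = None, out_scale: float = 0.1):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(input_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, output_dim, rng)
        self.fc2.weight.data *= out_scale
        self.input_dim = input_dim
        self.output_dim = output_dim

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu()).relu()


class SmallConvExtractor(Module):
    """Compact convolutional backbone for (n, H, W) grayscale images.

    Three strided valid convolutions followed by global average pooling;
    works for any input side of at least 32 pixels.
    """

    def __init__(self, output_dim: int = 32, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)

        def conv_params(c_out, c_in, k):
            scale = np.sqrt(2.0 / (c_in * k * k))
            w = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)), requires_grad=True)
            b = Tensor(np.zeros(c_out), requires_grad=True)
            return w, b

        self.w1, self.b1 = conv_params(8, 1, 5)
        self.w2, self.b2 = conv_params(16, 8, 3)
        self.w3, self.b3 = conv_params(output_dim, 16, 3)
        self.w3.data *= 0.1  # small-output init, as in MLPExtractor
        self.output_dim = output_dim

    def __call__(self, x) -> Tensor:
        data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
        if data.ndim == 3:  # (n, H, W) grayscale -> add channel axis
            x = Tensor(data[:, None, :, :])
        elif data.ndim == 4:
            x = x if isinstance(x, Tensor) else Tensor(data)
        else:
            raise ValueError("image batches must be (n, H, W) or (n, 1, H, W) arrays")
        if min(data.shape[-2], data.shape[-1]) < 32:
            raise ValueError("image side must be at least 32 pixels")
        h = x.conv2d(self.w1, self.b1, stride=2).relu()
        h = h.conv2d(self.w2, self.b2, stride=2).relu()
        h = h.conv2d(self.w3, self.b3, stride=2).relu()
        return h.global_avg_pool()


class SoftmaxHead(Module):
    """Linear layer + softmax producing a probability vector per sample."""

    def __init__(self, in_dim: int, n_outputs: int, rng: np.random.Generator):
        self.linear = Linear(in_dim, n_outputs, rng)
        self.n_outputs = n_outputs

    def logits(self, features: Tensor) -> Tensor:
        return self.linear(features)

    def __call__(self, features: Tensor) -> Tensor:
        return self.linear(features).softmax()


@dataclass
class ModelBundle:
    """Shared extractor + class-aware head + N per-domain classifiers."""

    extractor: Module
    class_aware_head: SoftmaxHead
    classifiers: List[SoftmaxHead]
    label_map: JointLabelMap
    fitted: bool = field(default=False)

    @classmethod
    def build(
        cls,
        *,
        n_domains: int,
        n_classes: int,
        input_dim: Optional[int] = None,
        input_kind: str = "features",
        feature_dim: int = 32,
        hidden_dim: int = 64,
        seed: int = 0,
        extractor: Optional[Module] = None,
    ) -> "ModelBundle":
        rng = np.random.default_rng(seed)
        if extractor is None:
            if input_kind == "features":
                if input_dim is None:
                    raise ValueError("feature inputs need input_dim")
                extractor = MLPExtractor(input_dim, feature_dim, hidden_dim, rng)
            elif input_kind == "images":
                extractor = SmallConvExtractor(feature_dim, rng)
            else:
                raise ValueError(f"unknown input kind {input_kind!r}")
        feat = extractor.output_dim
        label_map = JointLabelMap(n_domains=n_domains, n_classes=n_classes)
        head = SoftmaxHead(feat, label_map.n_joint, rng)
        classifiers = [SoftmaxHead(feat, n_classes, rng) for _ in range(n_domains)]
        return cls(extractor=extractor, class_aware_head=head,
                   classifiers=classifiers, label_map=label_map)

    def parameters(self) -> List[Tensor]:
        params = list(self.extractor.parameters())
        params += self.class_aware_head.parameters()
        for c in self.classifiers:
            params += c.parameters()
        return params

    def features(self, x) -> Tensor:
        return self.extractor(x if isinstance(x, Tensor) else Tensor(np.asarray(x)))

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading bundle state")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).copy()


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.001,
                 momentum: float = 0.9, weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
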