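"""Classifier contract and a small differentiable layer stack.

Every attribution method and metric in this package is model-agnostic: it sees
only a :class:`ClassifierHandle`, which exposes class *scores* (pre-softmax
logits), softmax probabilities, input gradients of a target score, and — for
CAM-family methods — convolutional feature maps with their score gradients.

The concrete network implementation here is a minimal numpy layer stack
(convolution, ReLU, pooling, linear) with hand-written forward and backward
passes.  Keeping the layers explicit serves two purposes: the fixture networks
used throughout the test-suite are exactly reproducible, and DeepLIFT's
Rescale rule (see :mod:`fundus_xai.attributions`) can propagate multipliers
layer by layer over the same primitives.

Conventions
-----------
* Images are ``(height, width, channels)`` float arrays with intensities in
  the handle's :class:`InputSpec` value range (``[0, 1]`` by default).
* ``scores`` are pre-softmax; "confidence" means the softmax probability.
* All computation is deterministic: two calls with identical inputs return
  bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import softmax

__all__ = [
    "DIFFERENTIABLE",
    "EXPOSES_FEATURE_MAPS",
    "FundusXAIError",
    "InputContractError",
    "CapabilityError",
    "ConfigurationError",
    "ModelFaultError",
    "InputSpec",
    "ClassifierHandle",
    "GradientFreeView",
    "Layer",
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "NetworkClassifier",
    "validate_image",
]

# Capability flags
DIFFERENTIABLE = "differentiable"
EXPOSES_FEATURE_MAPS = "exposes_feature_maps"


class FundusXAIError(Exception):
    """Base class for all package errors."""


class InputContractError(FundusXAIError):
    """An input violates the handle's declared spec (shape, range, finiteness)."""


class CapabilityError(FundusXAIError):
    """An operation was requested that the handle does not support."""


class ConfigurationError(FundusXAIError):
    """A configuration value is out of its valid range or inconsistent."""


class ModelFaultError(FundusXAIError):
    """The wrapped model produced non-finite or otherwise invalid outputs."""


@dataclass(frozen=True)
class InputSpec:
    """Input contract: spatial size, channel count, intensity range, classes.

    Defaults match the evaluation protocol: 224x224 RGB images scaled to
    [0, 1], five diabetic-retinopathy grades (0 = normal ... 4 = PDR).
    """

    height: int = 224
    width: int = 224
    channels: int = 3
    value_range: tuple[float, float] = (0.0, 1.0)
    num_classes: int = 5

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.channels, self.num_classes) <= 0:
            raise ConfigurationError("spec dimensions must be positive")
        lo, hi = self.value_range
        if not lo < hi:
            raise ConfigurationError("value_range lower bound must be < upper bound")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.channels)

    @property
    def span(self) -> float:
        lo, hi = self.value_range
        return hi - lo


def validate_image(image: np.ndarray, spec: InputSpec,
                   check_range: bool = False) -> np.ndarray:
    """Check an image against a spec; returns the array unchanged.

    The intensity-range check is opt-in: attribution methods legitimately
    evaluate gradients slightly outside the nominal range (SmoothGrad's
    noise is unclipped by design), while confidence evaluation on actual
    images enforces the full contract.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != spec.shape:
        raise InputContractError(
            f"image shape {image.shape} does not match spec {spec.shape}"
        )
    if not np.all(np.isfinite(image)):
        raise InputContractError("image contains non-finite values")
    if check_range:
        lo, hi = spec.value_range
        if image.min() < lo - 1e-9 or image.max() > hi + 1e-9:
            raise InputContractError(
                f"image intensities outside value_range [{lo}, {hi}]"
            )
    return image


class ClassifierHandle:
    """Opaque classifier satisfying the score/probability/gradient contract.

    Subclasses must implement :meth:`scores`; the differentiable and
    feature-map methods are optional and guarded by capability flags.
    """

    spec: InputSpec
    identity: str = "classifier"
    capabilities: frozenset[str] = frozenset()

    # -- core contract ----------------------------------------------------

    def scores(self, image: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores, shape ``(num_classes,)``."""
        raise NotImplementedError

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Softmax probabilities over classes; finite, nonnegative, sum to 1."""
        p = softmax(self.scores(image))
        if not np.all(np.isfinite(p)):
            raise ModelFaultError(f"{self.identity}: non-finite probabilities")
        return p

    def predict_confidence(self, image: np.ndarray, target: int) -> float:
        """Probability assigned to ``target`` — the perturbation-curve ordinate."""
        self._check_target(target)
        image = validate_image(image, self.spec, check_range=True)
        return float(self.predict_proba(image)[target])

    def score(self, image: np.ndarray, target: int) -> float:
        """Pre-softmax score of ``target`` — the attribution objective."""
        self._check_target(target)
        return float(self.scores(image)[target])

    # -- optional capabilities --------------------------------------------

    def input_gradient(self, image: np.ndarray, target: int) -> np.ndarray:
        """Gradient of the target-class score w.r.t. every input intensity."""
        raise CapabilityError(f"{self.identity} is not differentiable")

    def feature_maps(self, image: np.ndarray, layer: str | None = None) -> np.ndarray:
        """Stack of 2-D activation maps, shape ``(C, h, w)``."""
        raise CapabilityError(f"{self.identity} does not expose feature maps")

    def feature_map_gradients(
        self, image: np.ndarray, target: int, layer: str | None = None
    ) -> np.ndarray:
        """Gradient of the target score w.r.t. each activation, shape ``(C, h, w)``."""
        raise CapabilityError(f"{self.identity} does not expose feature maps")

    def without_gradients(self) -> "GradientFreeView":
        """A view of this handle with gradient access disabled.

        ScoreCAM is specified as gradient-free; running it through this view
        guarantees no gradient computation can occur.
        """
        return GradientFreeView(self)

    # -- helpers ----------------------------------------------------------

    def _check_target(self, target: int) -> None:
        if not 0 <= int(target) < self.spec.num_classes:
            raise InputContractError(
                f"target {target} outside [0, {self.spec.num_classes})"
            )


class GradientFreeView(ClassifierHandle):
    """Wrapper that forwards everything except gradient computation."""

    def __init__(self, base: ClassifierHandle):
        self._base = base
        self.spec = base.spec
        self.identity = base.identity + " (no-grad)"
        self.capabilities = base.capabilities - {DIFFERENTIABLE}

    def scores(self, image: np.ndarray) -> np.ndarray:
        return self._base.scores(image)

    def feature_maps(self, image: np.ndarray, layer: str | None = None) -> np.ndarray:
        return self._base.feature_maps(image, layer)

    def input_gradient(self, image: np.ndarray, target: int) -> np.ndarray:
        raise CapabilityError(f"{self.identity}: gradient tracking is disabled")

    def feature_map_gradients(
        self, image: np.ndarray, target: int, layer: str | None = None
    ) -> np.ndarray:
        raise CapabilityError(f"{self.identity}: gradient tracking is disabled")


# ---------------------------------------------------------------------------
# Layer stack
# ---------------------------------------------------------------------------


class Layer:
    """A primitive layer: stateless parameters, cached forward activations.

    ``forward`` caches whatever ``backward`` needs; ``backward`` returns the
    gradient w.r.t. the layer input and, when ``accumulate_param_grads`` is
    set, stores parameter gradients for the optimizer.  For linear layers the
    input gradient depends only on the weights, which is what lets DeepLIFT
    reuse ``backward`` for multiplier propagation.
    """

    name: str = "layer"

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(
        self, grad: np.ndarray, accumulate_param_grads: bool = False
    ) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def is_linear(self) -> bool:
        """True if the layer computes an affine function of its input."""
        return True

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def parameter_grads(self) -> dict[str, np.ndarray]:
        return {}


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (H, W, C) into (oh*ow, k*k*C) patch rows."""
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    H, W, C = xp.shape
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    cols = np.empty((oh, ow, k, k, C), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j, :] = xp[
                i : i + oh * stride : stride, j : j + ow * stride : stride, :
            ]
    return cols.reshape(oh * ow, k * k * C), (oh, ow)


def _col2im(gcols: np.ndarray, xshape, k: int, stride: int, pad: int, oh: int, ow: int):
    """Scatter-add patch-row gradients back onto the (padded) input grid."""
    H, W, C = xshape
    gxp = np.zeros((H + 2 * pad, W + 2 * pad, C), dtype=gcols.dtype)
    gc = gcols.reshape(oh, ow, k, k, C)
    for i in range(k):
        for j in range(k):
            gxp[
                i : i + oh * stride : stride, j : j + ow * stride : stride, :
            ] += gc[:, :, i, j, :]
    return gxp[pad : pad + H, pad : pad + W, :]


class Conv2d(Layer):
    """2-D convolution, channels-last, zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ksize: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ksize = ksize
        self.stride = stride
        self.pad = pad
        self.name = name
        fan_in = ksize * ksize * in_channels
        if rng is None:
            self.weight = np.zeros((ksize, ksize, in_channels, out_channels))
        else:
            self.weight = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                                     (ksize, ksize, in_channels, out_channels))
        self.bias = np.zeros(out_channels)
        self._cache = None
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, self.ksize, self.stride, self.pad)
        wmat = self.weight.reshape(-1, self.out_channels)
        y = cols @ wmat + self.bias
        self._cache = (cols, x.shape, oh, ow)
        return y.reshape(oh, ow, self.out_channels)

    def backward(self, grad, accumulate_param_grads=False):
        cols, xshape, oh, ow = self._cache
        g = grad.reshape(oh * ow, self.out_channels)
        wmat = self.weight.reshape(-1, self.out_channels)
        if accumulate_param_grads:
            self.gweight += (cols.T @ g).reshape(self.weight.shape)
            self.gbias += g.sum(axis=0)
        gcols = g @ wmat.T
        return _col2im(gcols, xshape, self.ksize, self.stride, self.pad, oh, ow)

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def parameter_grads(self):
        return {"weight": self.gweight, "bias": self.gbias}


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._x = None

    def forward(self, x):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, grad, accumulate_param_grads=False):
        return grad * (self._x > 0)

    @property
    def is_linear(self):
        return False


class GlobalAvgPool(Layer):
    """(H, W, C) -> (C,) spatial mean."""

    def __init__(self, name: str = "gap"):
        self.name = name
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(0, 1))

    def backward(self, grad, accumulate_param_grads=False):
        H, W, C = self._shape
        return np.broadcast_to(grad / (H * W), (H, W, C)).copy()


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.ravel()

    def backward(self, grad, accumulate_param_grads=False):
        return grad.reshape(self._shape)


class FeatureNorm(Layer):
    """Fixed affine feature standardization: ``(x - mean) / std``.

    In inference mode this is a plain affine map (so it sits inside the
    linear layer set DeepLIFT supports).  The statistics are identity at
    construction; training recalibrates them from the dataset's feature
    distribution (see the trainer), after which they stay frozen.
    """

    def __init__(self, n_features: int, name: str = "norm"):
        self.mean = np.zeros(n_features)
        self.std = np.ones(n_features)
        self.name = name

    def calibrate(self, features: np.ndarray, eps: float = 1e-6) -> None:
        features = np.asarray(features, dtype=float)
        self.mean = features.mean(axis=0)
        std = features.std(axis=0)
        # floor the scale so near-dead features are not amplified into noise
        self.std = np.maximum(std, 0.05 * std.max()) + eps

    def forward(self, x):
        return (x - self.mean) / self.std

    def backward(self, grad, accumulate_param_grads=False):
        return grad / self.std


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None, name: str = "fc"):
        if rng is None:
            self.weight = np.zeros((in_features, out_features))
        else:
            self.weight = rng.normal(0.0, math.sqrt(1.0 / in_features),
                                     (in_features, out_features))
        self.bias = np.zeros(out_features)
        self.name = name
        self._x = None
        self.gweight = np.zeros_like(self.weight)
        self.gbias = np.zeros_like(self.bias)

    def forward(self, x):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad, accumulate_param_grads=False):
        if accumulate_param_grads:
            self.gweight += np.outer(self._x, grad)
            self.gbias += grad
        return grad @ self.weight.T

    def parameters(self):
        return {"weight": self.weight, "bias": self.bias}

    def parameter_grads(self):
        return {"weight": self.gweight, "bias": self.gbias}


class NetworkClassifier(ClassifierHandle):
    """A feed-forward chain of :class:`Layer` objects satisfying the contract.

    Parameters
    ----------
    layers
        Chain applied in order; the last layer must produce a length-
        ``num_classes`` vector of scores.
    feature_layer
        Name of the layer whose *output* provides the CAM feature maps.
        Defaults to the output of the last layer that still has spatial
        extent (the last convolutional stage, post-nonlinearity).
    """

    def __init__(
        self,
        layers: Sequence[Layer],
        spec: InputSpec,
        identity: str = "network",
        feature_layer: str | None = None,
    ):
        self.layers = list(layers)
        self.spec = spec
        self.identity = identity
        caps = {DIFFERENTIABLE}
        self._feature_layer = feature_layer or self._default_feature_layer()
        if self._feature_layer is not None:
            caps.add(EXPOSES_FEATURE_MAPS)
        self.capabilities = frozenset(caps)

    def _default_feature_layer(self) -> str | None:
        last = None
        for layer in self.layers:
            if isinstance(layer, (Conv2d, ReLU)):
                last = layer.name
        return last

    def _layer_index(self, name: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.name == name:
                return i
        raise ConfigurationError(f"{self.identity}: unknown layer id {name!r}")

    # -- forward / backward ------------------------------------------------

    def scores(self, image: np.ndarray) -> np.ndarray:
        image = validate_image(image, self.spec)
        a = image
        for layer in self.layers:
            a = layer.forward(a)
        if not np.all(np.isfinite(a)):
            raise ModelFaultError(f"{self.identity}: non-finite scores")
        return a

    def forward_collect(self, image: np.ndarray) -> list[np.ndarray]:
        """Activations before each layer plus the final output (length L+1)."""
        acts = [validate_image(image, self.spec)]
        for layer in self.layers:
            acts.append(layer.forward(acts[-1]))
        return acts

    def input_gradient(self, image: np.ndarray, target: int) -> np.ndarray:
        self._check_target(target)
        scores = self.scores(image)  # populate caches
        g = np.zeros_like(scores)
        g[target] = 1.0
        for layer in reversed(self.layers):
            g = layer.backward(g)
        if not np.all(np.isfinite(g)):
            raise ModelFaultError(f"{self.identity}: non-finite gradient")
        return g

    def feature_maps(self, image: np.ndarray, layer: str | None = None) -> np.ndarray:
        idx = self._layer_index(layer or self._feature_layer)
        image = validate_image(image, self.spec)
        a = image
        for lyr in self.layers[: idx + 1]:
            a = lyr.forward(a)
        if a.ndim != 3:
            raise ConfigurationError(
                f"{self.identity}: layer {self.layers[idx].name!r} is not spatial"
            )
        return np.moveaxis(a, -1, 0)  # (C, h, w)

    def feature_map_gradients(
        self, image: np.ndarray, target: int, layer: str | None = None
    ) -> np.ndarray:
        self._check_target(target)
        idx = self._layer_index(layer or self._feature_layer)
        scores = self.scores(image)
        g = np.zeros_like(scores)
        g[target] = 1.0
        for lyr in reversed(self.layers[idx + 1 :]):
            g = lyr.backward(g)
        return np.moveaxis(g, -1, 0)

    # -- training support --------------------------------------------------

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.parameter_grads().values():
                g[...] = 0.0

    def backward_from_scores(self, gscores: np.ndarray) -> None:
        """Backpropagate an output-gradient, accumulating parameter grads."""
        g = gscores
        for layer in reversed(self.layers):
            g = layer.backward(g, accumulate_param_grads=True)
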