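"""Seven saliency / attribution methods, each returning a :class:`SaliencyMap`.

The methods split into three families:

* gradient-based — vanilla gradient, SmoothGrad, Integrated Gradients;
* reference-based attribution — SHAP (expected-gradients estimator) and
  DeepLIFT with the Rescale rule, both against a black baseline by default;
* class-activation mapping — Grad-CAM++ (gradient-weighted) and ScoreCAM
  (gradient-free, mask-and-score).

All methods attribute the *target-class score* (pre-softmax logit).  The
signed per-channel attribution is kept in ``raw``; ``map2d`` is the
channel-aggregated nonnegative saliency used by every downstream metric
(sum of absolute values over channels, which keeps negative evidence
visible).  Stochastic methods (SmoothGrad, SHAP) are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import softmax
from skimage.transform import resize

from .models import (
    DIFFERENTIABLE,
    EXPOSES_FEATURE_MAPS,
    CapabilityError,
    ClassifierHandle,
    ConfigurationError,
    Conv2d,
    FeatureNorm,
    Flatten,
    GlobalAvgPool,
    InputContractError,
    Linear,
    NetworkClassifier,
    ReLU,
    validate_image,
)

__all__ = [
    "SaliencyMap",
    "AttributionConfig",
    "aggregate_channels",
    "vanilla_gradient",
    "smoothgrad",
    "integrated_gradients",
    "shap_attribution",
    "deeplift_rescale",
    "gradcam_pp",
    "scorecam",
    "METHODS",
    "compute_saliency",
]


def aggregate_channels(raw: np.ndarray) -> np.ndarray:
    """Collapse a signed (H, W, C) attribution into a nonnegative 2-D map.

    ``map2d[p] = sum_c |raw[p, c]|`` — permutation-invariant over channels.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise InputContractError("attribution grid contains non-finite values")
    if raw.ndim == 2:
        return np.abs(raw)
    return np.abs(raw).sum(axis=-1)


@dataclass
class SaliencyMap:
    """Signed attribution plus its aggregated 2-D saliency."""

    raw: np.ndarray  # (H, W, C) signed
    map2d: np.ndarray  # (H, W) nonnegative
    method: str
    target: int

    @classmethod
    def from_raw(cls, raw: np.ndarray, method: str, target: int) -> "SaliencyMap":
        return cls(raw=np.asarray(raw, dtype=float),
                   map2d=aggregate_channels(raw), method=method, target=int(target))


@dataclass
class AttributionConfig:
    """Shared knobs for the attribution methods.

    baseline
        Reference input for IG/SHAP/DeepLIFT: the string ``"black"`` (an
        image at the lower bound of the value range) or an explicit array.
    ig_steps
        Midpoint-rule quadrature steps for Integrated Gradients.
    sg_samples / sg_sigma
        SmoothGrad sample count and noise std as a fraction of the intensity
        span.  Noise is *not* clipped to the valid range.
    shap_samples
        Monte-Carlo samples for the expected-gradients SHAP estimator.
    """

    baseline: object = "black"
    ig_steps: int = 32
    sg_samples: int = 25
    sg_sigma: float = 0.15
    shap_samples: int = 64
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ig_steps < 1 or self.sg_samples < 1 or self.shap_samples < 1:
            raise ConfigurationError("sample/step counts must be >= 1")
        if self.sg_sigma < 0:
            raise ConfigurationError("sg_sigma must be >= 0")


def resolve_baseline(config: AttributionConfig, handle: ClassifierHandle) -> np.ndarray:
    spec = handle.spec
    if isinstance(config.baseline, str):
        if config.baseline != "black":
            raise ConfigurationError(f"unknown baseline policy {config.baseline!r}")
        return np.full(spec.shape, spec.value_range[0], dtype=float)
    base = np.asarray(config.baseline, dtype=float)
    if base.shape != spec.shape:
        raise ConfigurationError(
            f"baseline shape {base.shape} does not match spec {spec.shape}"
        )
    return base


def _require(handle: ClassifierHandle, cap: str, method: str) -> None:
    if cap not in handle.capabilities:
        raise CapabilityError(f"{method} requires the {cap!r} capability "
                              f"but {handle.identity} lacks it")


# ---------------------------------------------------------------------------
# Gradient family
# ---------------------------------------------------------------------------


def vanilla_gradient(handle, image, target,
                     config: AttributionConfig | None = None) -> SaliencyMap:
    """Raw input gradient of the target score (Gradient / saliency method)."""
    _require(handle, DIFFERENTIABLE, "vanilla_gradient")
    raw = handle.input_gradient(image, target)
    return SaliencyMap.from_raw(raw, "gradient", target)


def smoothgrad(handle, image, target,
               config: AttributionConfig | None = None) -> SaliencyMap:
    """Mean gradient over Gaussian-perturbed copies of the input."""
    config = config or AttributionConfig()
    _require(handle, DIFFERENTIABLE, "smoothgrad")
    image = validate_image(image, handle.spec)
    if config.sg_sigma == 0.0:
        raw = handle.input_gradient(image, target)
        return SaliencyMap.from_raw(raw, "smoothgrad", target)
    rng = np.random.default_rng(config.rng_seed)
    sigma = config.sg_sigma * handle.spec.span
    acc = np.zeros(handle.spec.shape)
    for _ in range(config.sg_samples):
        noisy = image + rng.normal(0.0, sigma, image.shape)
        acc += handle.input_gradient(noisy, target)
    return SaliencyMap.from_raw(acc / config.sg_samples, "smoothgrad", target)


def integrated_gradients(handle, image, target,
                         config: AttributionConfig | None = None) -> SaliencyMap:
    """Path-integrated gradients from the baseline to the input.

    Midpoint Riemann rule over ``ig_steps`` equal subintervals of the
    straight-line path, so the completeness axiom
    ``sum(raw) = score(x) - score(baseline)`` holds to quadrature accuracy.
    """
    config = config or AttributionConfig()
    _require(handle, DIFFERENTIABLE, "integrated_gradients")
    image = validate_image(image, handle.spec)
    base = resolve_baseline(config, handle)
    delta = image - base
    acc = np.zeros(handle.spec.shape)
    m = config.ig_steps
    for k in range(m):
        alpha = (k + 0.5) / m
        acc += handle.input_gradient(base + alpha * delta, target)
    return SaliencyMap.from_raw(delta * acc / m, "integrated_gradients", target)


def shap_attribution(handle, image, target,
                     config: AttributionConfig | None = None) -> SaliencyMap:
    """Shapley-value attribution via the expected-gradients estimator.

    Samples a reference ``b`` from the baseline set and an interpolation
    coefficient ``alpha ~ U(0, 1)``, averaging ``(x - b) * grad`` at the
    interpolated point.  With a single baseline this is an unbiased
    Monte-Carlo estimate of Integrated Gradients.  Pixel-level references are
    used rather than superpixel surrogates, which blur the small, poorly
    delimited lesions typical of fundus images.
    """
    config = config or AttributionConfig()
    _require(handle, DIFFERENTIABLE, "shap_attribution")
    image = validate_image(image, handle.spec)
    if isinstance(config.baseline, (list, tuple)):
        if len(config.baseline) == 0:
            raise ConfigurationError("SHAP baseline set is empty")
        baselines = [
            resolve_baseline(replace(config, baseline=b), handle)
            for b in config.baseline
        ]
    else:
        baselines = [resolve_baseline(config, handle)]
    rng = np.random.default_rng(config.rng_seed)
    acc = np.zeros(handle.spec.shape)
    for _ in range(config.shap_samples):
        b = baselines[rng.integers(len(baselines))]
        alpha = rng.uniform()
        delta = image - b
        acc += delta * handle.input_gradient(b + alpha * delta, target)
    return SaliencyMap.from_raw(acc / config.shap_samples, "shap", target)


# ---------------------------------------------------------------------------
# DeepLIFT (Rescale rule)
# ---------------------------------------------------------------------------

_DEEPLIFT_EPS = 1e-7
_LINEAR_LAYERS = (Conv2d, Linear, GlobalAvgPool, Flatten, FeatureNorm)


def deeplift_rescale(handle, image, target,
                     config: AttributionConfig | None = None) -> SaliencyMap:
    """DeepLIFT contributions by backward multiplier propagation.

    Linear layers propagate multipliers exactly like gradients (bias terms
    cancel in the activation differences); ReLU layers use the Rescale rule:
    multiplier = Δoutput/Δinput where ``|Δinput| > eps``, else the local
    gradient.  On a chain of linear layers and ReLUs this satisfies
    summation-to-delta exactly: ``sum(raw) = score(x) - score(baseline)``.
    """
    config = config or AttributionConfig()
    if not isinstance(handle, NetworkClassifier):
        raise CapabilityError(
            f"deeplift_rescale needs a layer-structured network, got {handle.identity}"
        )
    image = validate_image(image, handle.spec)
    base = resolve_baseline(config, handle)
    for layer in handle.layers:
        if not isinstance(layer, _LINEAR_LAYERS + (ReLU,)):
            raise CapabilityError(
                f"deeplift_rescale: unsupported layer {layer.name!r} "
                f"({type(layer).__name__})"
            )
    acts_b = handle.forward_collect(base)
    acts_x = handle.forward_collect(image)  # leaves caches at x for backward()
    g = np.zeros_like(acts_x[-1])
    g[target] = 1.0
    for i in range(len(handle.layers) - 1, -1, -1):
        layer = handle.layers[i]
        if isinstance(layer, ReLU):
            dx = acts_x[i] - acts_b[i]
            dy = acts_x[i + 1] - acts_b[i + 1]
            local = (acts_x[i] > 0).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                mult = np.where(np.abs(dx) > _DEEPLIFT_EPS, dy / dx, local)
            g = g * mult
        else:
            g = layer.backward(g)
    raw = g * (image - base)
    return SaliencyMap.from_raw(raw, "deeplift", target)


# ---------------------------------------------------------------------------
# CAM family
# ---------------------------------------------------------------------------


def _upsample(map2d: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling to the input grid."""
    if map2d.shape == shape:
        return np.asarray(map2d, dtype=float)
    return resize(map2d.astype(float), shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def gradcam_pp(handle, image, target, layer: str | None = None) -> SaliencyMap:
    """Grad-CAM++: pixel-wise weighted combination of activation gradients.

    Per-map weights come from the closed-form combination of the first,
    second, and third powers of the activation gradients
    (``alpha = g^2 / (2 g^2 + sum(A g^3) + 1e-8)``, weight =
    ``sum(alpha * relu(g))``); the map is the ReLU of the weighted activation
    sum, bilinearly upsampled to the input grid.
    """
    _require(handle, EXPOSES_FEATURE_MAPS, "gradcam_pp")
    _require(handle, DIFFERENTIABLE, "gradcam_pp")
    A = handle.feature_maps(image, layer)  # (C, h, w)
    G = handle.feature_map_gradients(image, target, layer)
    g2 = G * G
    g3 = g2 * G
    denom = 2.0 * g2 + (A * g3).sum(axis=(1, 2), keepdims=True) + 1e-8
    alpha = g2 / denom
    weights = (alpha * np.maximum(G, 0.0)).sum(axis=(1, 2))  # (C,)
    cam = np.maximum(np.tensordot(weights, A, axes=1), 0.0)
    map2d = _upsample(cam, (handle.spec.height, handle.spec.width))
    return SaliencyMap.from_raw(map2d[..., None], "gradcam++", target)


def scorecam(handle, image, target, layer: str | None = None) -> SaliencyMap:
    """ScoreCAM: gradient-free mask-and-score feature-map weighting.

    Each activation map is min-max normalized, upsampled, and used as a soft
    mask on the image; the map's weight is the softmax (over maps) of the
    target-score increase of the masked image relative to the black baseline.
    Runs entirely through a gradient-disabled view of the handle.
    """
    _require(handle, EXPOSES_FEATURE_MAPS, "scorecam")
    h = handle.without_gradients()
    image = validate_image(image, h.spec)
    A = h.feature_maps(image, layer)  # (C, h, w)
    shape = (h.spec.height, h.spec.width)
    black = np.full(h.spec.shape, h.spec.value_range[0], dtype=float)
    base_score = h.score(black, target)
    masks = np.zeros((A.shape[0],) + shape)
    increases = np.zeros(A.shape[0])
    for k in range(A.shape[0]):
        amin, amax = A[k].min(), A[k].max()
        if amax > amin:
            masks[k] = _upsample((A[k] - amin) / (amax - amin), shape)
        # constant maps keep an all-zero mask: the masked image is the black
        # baseline, the score increase is 0, and no spatial structure enters
        increases[k] = h.score(image * masks[k][..., None], target) - base_score
    if len(increases) > 1 and np.ptp(increases) == 0.0:
        # no mask changes the score (constant-output model, or an all-zero
        # feature stack): no map carries evidence, return the zero map
        return SaliencyMap.from_raw(np.zeros(shape + (1,)), "scorecam", target)
    weights = softmax(increases)
    cam = np.maximum(np.tensordot(weights, masks, axes=1), 0.0)
    return SaliencyMap.from_raw(cam[..., None], "scorecam", target)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

METHODS = {
    "gradient": vanilla_gradient,
    "smoothgrad": smoothgrad,
    "integrated_gradients": integrated_gradients,
    "shap": shap_attribution,
    "deeplift": deeplift_rescale,
    "gradcam++": gradcam_pp,
    "scorecam": scorecam,
}

#: methods whose perturbation curves the evaluation protocol found unstable;
#: excluded from the saliency-quality tables by default
CAM_METHODS = ("gradcam++", "scorecam")


def compute_saliency(handle, image, target, method: str,
                     config: AttributionConfig | None = None,
                     layer: str | None = None) -> SaliencyMap:
    """Dispatch a method by name."""
    if method not in METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        )
    if method in CAM_METHODS:
        return METHODS[method](handle, image, target, layer)
    return METHODS[method](handle, image, target, config)
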