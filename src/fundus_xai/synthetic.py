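"""Synthetic fundus scenes and fixture classifiers with known structure.

The evaluation protocol was designed around a clinical fundus dataset and
trained networks that cannot ship with a library.  This module generates
stylized stand-ins at desk scale:

* :func:`generate_fundus` renders a circular fundus field with a radial
  background gradient, an optic disc, vessel-like dark curves, and spot
  lesions of two classes (microaneurysms: small dark discs; hemorrhages:
  dark multi-lobed blotches) with pixel-exact masks, polygon annotations,
  and a documented count-based grade label.  Scenes exercise geometry and
  saliency-mass placement, not clinical appearance.
* :func:`make_planted_model` builds classifiers whose decision structure is
  known in closed form — the oracles behind the gradient, completeness,
  perturbation and CAM tests.
* :func:`train_tiny_cnn` trains the 2-conv fixture network on generated
  scenes with seeded, fully deterministic numpy Adam.

Everything is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .lesions import LesionMaskSet, PolygonAnnotation
from .models import (
    DIFFERENTIABLE,
    EXPOSES_FEATURE_MAPS,
    ClassifierHandle,
    ConfigurationError,
    Conv2d,
    FeatureNorm,
    Flatten,
    FundusXAIError,
    GlobalAvgPool,
    InputSpec,
    Linear,
    NetworkClassifier,
    ReLU,
    validate_image,
)

__all__ = [
    "GenerationError",
    "TrainingError",
    "FundusSceneSpec",
    "FundusScene",
    "PlantedModelSpec",
    "generate_fundus",
    "grade_from_counts",
    "make_planted_model",
    "make_region_fraction_model",
    "make_intensity_linear_model",
    "make_tiny_cnn",
    "make_spot_detector",
    "train_tiny_cnn",
    "training_scenes",
    "training_accuracy",
    "scene_spec_for_grade",
]


class GenerationError(FundusXAIError):
    """Scene generation failed (no feasible lesion placement)."""


class TrainingError(FundusXAIError):
    """Fixture training got a degenerate dataset."""


@dataclass(frozen=True)
class FundusSceneSpec:
    """Parameters of one synthetic fundus scene.

    Lesion size ranges follow the appearance they emulate: microaneurysms
    are small dark discs (2-5 px radius at 224 resolution), hemorrhages are
    larger dark blotches (4-10 px).
    """

    size: int = 224
    fov_radius_frac: float = 0.48
    vessel_count: int = 4
    vessel_curvature: float = 0.15
    n_microaneurysms: int = 0
    n_hemorrhages: int = 0
    ma_radius: tuple[int, int] = (2, 5)
    hem_radius: tuple[int, int] = (4, 10)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_microaneurysms < 0 or self.n_hemorrhages < 0:
            raise ConfigurationError("lesion counts must be >= 0")
        if min(self.ma_radius) <= 0 or min(self.hem_radius) <= 0:
            raise ConfigurationError("lesion radii must be positive")


@dataclass
class FundusScene:
    image: np.ndarray  # (S, S, 3) in [0, 1]
    masks: LesionMaskSet
    grade: int
    annotations: list[PolygonAnnotation]
    spec: FundusSceneSpec


def grade_from_counts(n_microaneurysms: int, n_hemorrhages: int) -> int:
    """Simplified severity surrogate of the clinical (ICDR-style) scale.

    No lesions -> 0 (normal); microaneurysms only -> 1 (mild NPDR, which is
    clinically defined by microaneurysms alone); hemorrhages escalate the
    grade with their count (1-3 -> 2, 4-9 -> 3, >= 10 -> 4).  This is a
    documented counting rule for synthetic labels, not a clinical grader.
    """
    if n_hemorrhages == 0:
        return 0 if n_microaneurysms == 0 else 1
    if n_hemorrhages <= 3:
        return 2
    if n_hemorrhages <= 9:
        return 3
    return 4


def _circle_polygon(center, radius, bound, k=16):
    angles = np.linspace(0.0, 2 * math.pi, k, endpoint=False)
    verts = np.stack([
        center[0] + radius * np.sin(angles),
        center[1] + radius * np.cos(angles),
    ], axis=1)
    return np.clip(verts, 0.0, bound)


def generate_fundus(spec: FundusSceneSpec) -> FundusScene:
    """Render one scene; deterministic given ``spec.rng_seed``.

    The RNG stream is consumed in a fixed order (background, disc, vessels,
    then lesions), so the zero-lesion render of the same seed is pixel-
    identical outside the lesion masks.
    """
    rng = np.random.default_rng(spec.rng_seed)
    S = spec.size
    cy = cx = S / 2.0
    R = spec.fov_radius_frac * S

    rr, cc = np.meshgrid(np.arange(S) + 0.5, np.arange(S) + 0.5, indexing="ij")
    d = np.hypot(rr - cy, cc - cx)
    fov = d <= R

    # background: warm radial gradient, dark rim, black outside the field
    base_color = np.array([0.82, 0.40, 0.12])
    shade = np.clip(1.0 - 0.35 * (d / R) ** 2, 0.0, 1.0)
    img = base_color[None, None, :] * shade[..., None]
    img[~fov] = 0.0

    # optic disc: bright circle toward the nasal side
    disc_c = (cy, cx + 0.55 * R)
    disc_r = 0.09 * S
    disc = np.hypot(rr - disc_c[0], cc - disc_c[1]) <= disc_r
    img[disc & fov] = np.array([0.95, 0.85, 0.55])

    # vessels: dark random-curvature walks out of the disc
    vessel = np.zeros((S, S), dtype=bool)
    for _ in range(spec.vessel_count):
        ang = rng.uniform(0.0, 2 * math.pi)
        r, c = disc_c
        for _step in range(int(2.2 * R)):
            ang += rng.normal(0.0, spec.vessel_curvature)
            r += math.sin(ang)
            c += math.cos(ang)
            ir, ic = int(r), int(c)
            if not (0 <= ir < S and 0 <= ic < S) or d[ir, ic] > 0.97 * R:
                break
            vessel[ir, ic] = True
    vessel = binary_dilation(vessel) & fov & ~disc
    img[vessel] *= np.array([0.62, 0.50, 0.55])

    # lesions: rejection-placed dark spots with pixel-exact masks
    class_masks: dict[str, np.ndarray] = {}
    annotations: list[PolygonAnnotation] = []
    log = []

    sep = max(1.0, 2.0 * S / 224.0)  # placement margins scale with resolution

    plan = (
        [("microaneurysm", spec.ma_radius, 1)] * spec.n_microaneurysms
        + [("hemorrhage", spec.hem_radius, 3)] * spec.n_hemorrhages
    )
    colors = {"microaneurysm": np.array([0.45, 0.08, 0.06]),
              "hemorrhage": np.array([0.38, 0.05, 0.05])}

    # choose all positions first; a stuck layout is discarded and resampled
    # whole, so an unlucky early placement cannot wedge the scene
    layout = None
    for _restart in range(100):
        attempt, ok = [], True
        for lesion_class, (lo, hi), n_lobes in plan:
            rad = int(rng.integers(lo, hi + 1))
            eff = 1.4 * rad if n_lobes > 1 else float(rad)
            for _try in range(200):
                ang = rng.uniform(0.0, 2 * math.pi)
                rho = (0.94 * R - eff - 1) * math.sqrt(rng.uniform())
                lr = cy + rho * math.sin(ang)
                lc = cx + rho * math.cos(ang)
                if math.hypot(lr - disc_c[0], lc - disc_c[1]) < disc_r + eff + sep:
                    continue
                if any(math.hypot(lr - pr, lc - pc) < eff + pe + sep
                       for _cls, pr, pc, pe, _rad, _n in attempt):
                    continue
                attempt.append((lesion_class, lr, lc, eff, rad, n_lobes))
                break
            else:
                ok = False
                break
        if ok:
            layout = attempt
            break
    if layout is None:
        raise GenerationError(
            f"no feasible lesion layout for {len(plan)} lesions at size {S}"
        )

    for lesion_class, lr, lc, eff, rad, n_lobes in layout:
        mask = np.zeros((S, S), dtype=bool)
        centers = [(lr, lc)]
        for _ in range(n_lobes - 1):
            centers.append((lr + rng.uniform(-0.6, 0.6) * rad,
                            lc + rng.uniform(-0.6, 0.6) * rad))
        for k, (mr, mc) in enumerate(centers):
            lobe_r = rad if k == 0 else 0.75 * rad
            mask |= np.hypot(rr - mr, cc - mc) <= lobe_r
        mask &= fov
        img[mask] = colors[lesion_class]
        cm = class_masks.setdefault(lesion_class, np.zeros((S, S), dtype=bool))
        cm |= mask
        annotations.append(PolygonAnnotation(
            vertices=_circle_polygon((lr, lc), eff + 1.0, S),
            lesion_class=lesion_class))
        log.append(((int(lr), int(lc)), lesion_class))

    img = np.clip(img, 0.0, 1.0)
    grade = grade_from_counts(spec.n_microaneurysms, spec.n_hemorrhages)
    return FundusScene(image=img,
                       masks=LesionMaskSet(class_masks=class_masks,
                                           placement_log=log),
                       grade=grade, annotations=annotations, spec=spec)


def scene_spec_for_grade(grade: int, seed: int, size: int = 224,
                         rng: np.random.Generator | None = None) -> FundusSceneSpec:
    """A scene spec whose lesion counts realize the requested grade."""
    rng = rng or np.random.default_rng(seed)
    scale = max(size / 224.0, 0.15)
    ma_r = (max(1, round(2 * scale)), max(2, round(5 * scale)))
    hem_r = (max(2, round(4 * scale)), max(3, round(10 * scale)))
    if grade == 0:
        ma, hem = 0, 0
    elif grade == 1:
        ma, hem = int(rng.integers(3, 7)), 0
    elif grade == 2:
        ma, hem = int(rng.integers(2, 6)), int(rng.integers(1, 4))
    elif grade == 3:
        ma, hem = int(rng.integers(2, 6)), int(rng.integers(4, 8))
    elif grade == 4:
        ma, hem = int(rng.integers(0, 4)), int(rng.integers(10, 13))
    else:
        raise ConfigurationError(f"grade {grade} outside 0-4")
    return FundusSceneSpec(size=size, n_microaneurysms=ma, n_hemorrhages=hem,
                           ma_radius=ma_r, hem_radius=hem_r, rng_seed=seed)


# ---------------------------------------------------------------------------
# Planted models
# ---------------------------------------------------------------------------


@dataclass
class PlantedModelSpec:
    """Recipe for a fixture classifier.

    kind
        ``region_fraction`` — class-1 probability is the mean intensity
        inside ``region``: the analytic oracle for perturbation/AOPC tests.
        ``intensity_linear`` — softmax over per-pixel linear functionals
        with known weights: the closed-form oracle for gradient methods.
        ``tiny_cnn`` — a 2-conv + 1-linear network with seeded weights
        exposing feature maps: the host for the CAM and DeepLIFT tests.
        ``spot_detector`` — a gradient-free dark-spot detector exposing one
        feature map: the planted detector for the trend experiment.
    """

    kind: str = "tiny_cnn"
    region: np.ndarray | None = None
    weights_seed: int = 0
    input_spec: InputSpec = field(default_factory=InputSpec)


class RegionFractionModel(ClassifierHandle):
    """Class-1 probability = mean intensity inside a planted region.

    The remaining probability mass is split evenly over the other classes,
    so outputs are valid probabilities by construction and the target-class
    confidence falls exactly linearly as region pixels are masked to black.
    For this oracle the "score" *is* the probability.
    """

    capabilities = frozenset({DIFFERENTIABLE})

    def __init__(self, region: np.ndarray, spec: InputSpec):
        region = np.asarray(region, dtype=bool)
        if region.shape != (spec.height, spec.width):
            raise ConfigurationError("region shape does not match spec")
        if not region.any():
            raise ConfigurationError("region_fraction model needs a non-empty region")
        self.region = region
        self.spec = spec
        self.identity = "region_fraction"
        self._norm = float(region.sum()) * spec.channels

    def scores(self, image: np.ndarray) -> np.ndarray:
        image = validate_image(image, self.spec)
        m = float(image[self.region].sum()) / self._norm
        lo, hi = self.spec.value_range
        m = min(max((m - lo) / (hi - lo), 0.0), 1.0)
        nc = self.spec.num_classes
        out = np.full(nc, (1.0 - m) / (nc - 1))
        out[1] = m
        return out

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        return self.scores(image)  # scores are probabilities by construction

    def input_gradient(self, image: np.ndarray, target: int) -> np.ndarray:
        self._check_target(target)
        validate_image(image, self.spec)
        g = np.zeros(self.spec.shape)
        unit = 1.0 / (self._norm * self.spec.span)
        if target == 1:
            g[self.region] = unit
        else:
            g[self.region] = -unit / (self.spec.num_classes - 1)
        return g


class SpotDetectorModel(ClassifierHandle):
    """Hand-built dark-spot detector: gradient-free, one feature map.

    Darkness is background subtraction — ReLU(smoothed intensity - local
    intensity) inside the field of view — which lights up exactly the small
    dark structures (lesions, vessels).  Class-1 score is the mean darkness;
    the feature map is the block-averaged darkness grid.
    """

    capabilities = frozenset({EXPOSES_FEATURE_MAPS})

    def __init__(self, spec: InputSpec, pool: int = 8, bg_sigma: float | None = None,
                 gain: float = 200.0):
        self.spec = spec
        self.identity = "spot_detector"
        self.pool = pool
        self.bg_sigma = bg_sigma if bg_sigma is not None else max(3.0, spec.height / 28.0)
        self.gain = gain

    def _darkness(self, image: np.ndarray) -> np.ndarray:
        image = validate_image(image, self.spec)
        inten = image.mean(axis=-1)
        bg = gaussian_filter(inten, sigma=self.bg_sigma)
        dark = np.maximum(bg - inten, 0.0)
        dark[inten < 0.05] = 0.0  # ignore the black surround outside the FOV
        return dark

    def scores(self, image: np.ndarray) -> np.ndarray:
        dark = self._darkness(image)
        out = np.zeros(self.spec.num_classes)
        out[1] = self.gain * float(dark.mean())
        return out

    def feature_maps(self, image: np.ndarray, layer: str | None = None) -> np.ndarray:
        if layer not in (None, "darkness"):
            raise ConfigurationError(f"{self.identity}: unknown layer id {layer!r}")
        dark = self._darkness(image)
        p = self.pool
        H, W = dark.shape
        h, w = H // p, W // p
        pooled = dark[: h * p, : w * p].reshape(h, p, w, p).mean(axis=(1, 3))
        return pooled[None, :, :]


def make_region_fraction_model(region: np.ndarray,
                               spec: InputSpec | None = None) -> RegionFractionModel:
    return RegionFractionModel(region, spec or InputSpec())


def make_intensity_linear_model(spec: InputSpec | None = None,
                                seed: int = 0) -> NetworkClassifier:
    spec = spec or InputSpec()
    rng = np.random.default_rng(seed)
    n = spec.height * spec.width * spec.channels
    net = NetworkClassifier(
        [Flatten(), Linear(n, spec.num_classes, rng=rng)],
        spec=spec, identity="intensity_linear")
    return net


def make_tiny_cnn(spec: InputSpec | None = None, seed: int = 0,
                  width: int = 8) -> NetworkClassifier:
    """2 conv (stride 2) + ReLU stages, global average pool, linear head.

    A :class:`FeatureNorm` layer (identity until calibrated by the trainer)
    standardizes the pooled features; in inference mode it is a fixed affine
    map, so the whole chain stays inside DeepLIFT's supported layer set.
    """
    spec = spec or InputSpec()
    rng = np.random.default_rng(seed)
    layers = [
        Conv2d(spec.channels, width, ksize=3, stride=2, pad=1, rng=rng, name="conv1"),
        ReLU(name="relu1"),
        Conv2d(width, width, ksize=3, stride=2, pad=1, rng=rng, name="conv2"),
        ReLU(name="relu2"),
        GlobalAvgPool(name="gap"),
        FeatureNorm(width, name="norm"),
        Linear(width, spec.num_classes, rng=rng, name="fc"),
    ]
    return NetworkClassifier(layers, spec=spec, identity="tiny_cnn",
                             feature_layer="relu2")


def make_spot_detector(spec: InputSpec | None = None, **kwargs) -> SpotDetectorModel:
    return SpotDetectorModel(spec or InputSpec(), **kwargs)


def make_planted_model(spec: PlantedModelSpec) -> ClassifierHandle:
    """Build a fixture classifier from its recipe."""
    if spec.kind == "region_fraction":
        if spec.region is None:
            raise ConfigurationError("region_fraction needs a region mask")
        return make_region_fraction_model(spec.region, spec.input_spec)
    if spec.kind == "intensity_linear":
        return make_intensity_linear_model(spec.input_spec, spec.weights_seed)
    if spec.kind == "tiny_cnn":
        return make_tiny_cnn(spec.input_spec, spec.weights_seed)
    if spec.kind == "spot_detector":
        return make_spot_detector(spec.input_spec)
    raise ConfigurationError(f"unknown planted-model kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Seeded training of the tiny CNN
# ---------------------------------------------------------------------------


def _scene_pairs(scenes):
    pairs = []
    for s in scenes:
        if isinstance(s, FundusScene):
            pairs.append((s.image, s.grade))
        else:
            pairs.append((np.asarray(s[0], dtype=float), int(s[1])))
    return pairs


def training_scenes(n_per_class: int = 100, seed: int = 0,
                    size: int = 48) -> list[FundusScene]:
    """Lesion-count-separable training set: lesion-free vs moderate scenes.

    Pairs of grade-0 scenes and grade-2 scenes (2-4 microaneurysms plus 1-3
    hemorrhages, at sizes that stay visible after the network's stride-4
    downsampling) — the separable-by-construction task the trained fixture
    is verified on.
    """
    scenes = []
    for i in range(n_per_class):
        scenes.append(generate_fundus(FundusSceneSpec(size=size,
                                                      rng_seed=seed + i)))
        rng = np.random.default_rng(seed + 20_000 + i)
        scenes.append(generate_fundus(FundusSceneSpec(
            size=size,
            n_microaneurysms=int(rng.integers(2, 5)),
            n_hemorrhages=int(rng.integers(1, 4)),
            ma_radius=(2, 3), hem_radius=(3, 4),
            rng_seed=seed + 10_000 + i)))
    return scenes


def train_tiny_cnn(scenes, epochs: int = 5, seed: int = 0,
                   lr: float = 3e-3, width: int = 16) -> NetworkClassifier:
    """Train the tiny CNN on generated scenes with deterministic numpy Adam.

    Procedure: calibrate the feature-normalization layer once from the
    initial pooled features, run per-sample cross-entropy Adam with seeded
    shuffling, and return the Polyak (tail) average of the final epoch's
    iterates, which removes single-step gradient noise from the endpoint.
    Two runs with the same inputs and seed produce identical final weights.
    """
    pairs = _scene_pairs(scenes)
    if not pairs:
        raise TrainingError("empty dataset")
    labels = sorted({y for _, y in pairs})
    if len(labels) < 2:
        raise TrainingError("training needs at least 2 classes present")
    size = pairs[0][0].shape[0]
    spec = InputSpec(height=size, width=size,
                     channels=pairs[0][0].shape[2],
                     num_classes=max(5, max(labels) + 1))
    net = make_tiny_cnn(spec, seed=seed, width=width)
    rng = np.random.default_rng(seed + 1)

    params, moments = [], []
    for layer in net.layers:
        for name in layer.parameters():
            params.append((layer, name))
            moments.append([np.zeros_like(layer.parameters()[name]),
                            np.zeros_like(layer.parameters()[name])])
    norm = next(l for l in net.layers if isinstance(l, FeatureNorm))
    gap_index = next(i for i, l in enumerate(net.layers) if l.name == "gap")

    feats = []
    for x, _y in pairs:
        a = x
        for layer in net.layers[: gap_index + 1]:
            a = layer.forward(a)
        feats.append(a)
    norm.calibrate(np.asarray(feats))

    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    tail_avg = [np.zeros_like(layer.parameters()[name]) for layer, name in params]
    n_avg = 0
    for epoch in range(epochs):
        for i in rng.permutation(len(pairs)):
            image, label = pairs[i]
            scores = net.scores(image)
            p = np.exp(scores - scores.max())
            p /= p.sum()
            g = p.copy()
            g[label] -= 1.0
            net.zero_grad()
            net.backward_from_scores(g)
            t += 1
            for (layer, name), mv in zip(params, moments):
                grad = layer.parameter_grads()[name]
                mv[0][...] = b1 * mv[0] + (1 - b1) * grad
                mv[1][...] = b2 * mv[1] + (1 - b2) * grad * grad
                mhat = mv[0] / (1 - b1 ** t)
                vhat = mv[1] / (1 - b2 ** t)
                layer.parameters()[name][...] -= lr * mhat / (np.sqrt(vhat) + eps)
            if epoch == epochs - 1:
                n_avg += 1
                for acc, (layer, name) in zip(tail_avg, params):
                    acc += (layer.parameters()[name] - acc) / n_avg
    for acc, (layer, name) in zip(tail_avg, params):
        layer.parameters()[name][...] = acc
    return net


def training_accuracy(handle: ClassifierHandle, scenes) -> float:
    pairs = _scene_pairs(scenes)
    hits = sum(int(np.argmax(handle.predict_proba(x))) == y for x, y in pairs)
    return hits / len(pairs)
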