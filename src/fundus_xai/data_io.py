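"""Readers/writers, run configuration, and the end-to-end pipeline.

File formats
------------
* Images: JPEG/PNG, loaded with Pillow, bilinearly resized to the spec
  resolution and scaled to [0, 1] (grayscale inputs are replicated to RGB
  with a warning).
* Annotations: a JSON list of ``{"lesion_class": ..., "vertices": [[r, c],
  ...]}`` records; rasterized per class via the polygon module.
* Masks: binary PNGs (any nonzero pixel counts as lesion).
* Manifests: JSON with one record per image (path, grade, optional
  annotation/mask paths) plus a free-form provenance block.
* Saliency arrays: ``.npz`` (lossless float) with a JSON metadata sidecar;
  a min-max-scaled grayscale PNG is written alongside for visualization.
* Reports: one CSV per grade (columns ``Model, Label, Entropy, Recall,
  Dice, AOPC_Score``; 4-decimal display) and a full-precision JSON document.

All randomness in a pipeline run flows from the single ``RunConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .attributions import CAM_METHODS, METHODS, AttributionConfig, SaliencyMap
from .lesions import LESION_CLASSES, AnnotationError, LesionMaskSet, PolygonAnnotation, polygon_to_mask
from .metrics import EvaluationRecord, evaluate_batch, summarize_records
from .models import ClassifierHandle, ConfigurationError, FundusXAIError, InputContractError, InputSpec

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "RunConfig",
    "load_image",
    "load_annotations",
    "load_mask_png",
    "save_mask_png",
    "save_saliency",
    "load_saliency",
    "summarize_manifest",
    "summarize_grade_counts",
    "run_pipeline",
]

logger = logging.getLogger("fundus_xai")

GRADE_NAMES = ("Normal", "Mild NPDR", "Moderate NPDR", "Severe NPDR", "PDR")


# ---------------------------------------------------------------------------
# Images, masks, annotations
# ---------------------------------------------------------------------------


def load_image(path, spec: InputSpec | None = None) -> np.ndarray:
    """Load a JPEG/PNG, resize bilinearly to the spec, scale to [0, 1]."""
    spec = spec or InputSpec()
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I", "I;16"):
                warnings.warn(f"{path.name}: grayscale input replicated to 3 channels",
                              stacklevel=2)
            im = im.convert("RGB")
            im = im.resize((spec.width, spec.height), Image.Resampling.BILINEAR)
            arr = np.asarray(im, dtype=float) / 255.0
    except (OSError, SyntaxError) as exc:
        raise InputContractError(f"cannot read image {path}: {exc}") from exc
    lo, hi = spec.value_range
    return lo + arr * (hi - lo)


def load_mask_png(path) -> np.ndarray:
    """Binary mask from a PNG: nonzero pixels are lesion."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def load_annotations(path, shape: tuple[int, int]) -> LesionMaskSet:
    """Rasterize a polygon-annotation JSON file into per-class masks."""
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise AnnotationError(f"{path}: expected a JSON list of annotations")
    class_masks: dict[str, np.ndarray] = {}
    for i, rec in enumerate(records):
        try:
            ann = PolygonAnnotation(vertices=np.asarray(rec["vertices"], dtype=float),
                                    lesion_class=rec["lesion_class"])
        except (KeyError, TypeError, AnnotationError) as exc:
            raise AnnotationError(f"{path}: record {i}: {exc}") from exc
        mask = polygon_to_mask(ann, shape)
        cm = class_masks.setdefault(ann.lesion_class, np.zeros(shape, dtype=bool))
        cm |= mask
    return LesionMaskSet(class_masks=class_masks)


def save_annotations(annotations, path) -> None:
    records = [{"lesion_class": a.lesion_class,
                "vertices": np.asarray(a.vertices, dtype=float).tolist()}
               for a in annotations]
    Path(path).write_text(json.dumps(records, indent=2))


# ---------------------------------------------------------------------------
# Saliency array round-trip
# ---------------------------------------------------------------------------


def save_saliency(sal: SaliencyMap, stem, meta: dict | None = None) -> None:
    """Write ``stem.npz`` (exact float), ``stem.json`` (metadata),
    ``stem.png`` (min-max scaled visualization)."""
    stem = Path(stem)
    np.savez(stem.with_suffix(".npz"), raw=sal.raw, map2d=sal.map2d)
    record = {"method": sal.method, "target": sal.target}
    record.update(meta or {})
    stem.with_suffix(".json").write_text(json.dumps(record, indent=2))
    m = sal.map2d
    lo, hi = float(m.min()), float(m.max())
    vis = np.zeros_like(m) if hi <= lo else (m - lo) / (hi - lo)
    Image.fromarray((vis * 255).astype(np.uint8)).save(stem.with_suffix(".png"))


def load_saliency(stem) -> SaliencyMap:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as data:
        raw, map2d = data["raw"], data["map2d"]
    meta = json.loads(stem.with_suffix(".json").read_text())
    return SaliencyMap(raw=raw, map2d=map2d, method=meta["method"],
                       target=int(meta["target"]))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class ManifestRecord:
    image: str
    grade: int
    annotation: str | None = None
    masks: dict[str, str] | None = None

    def __post_init__(self):
        if not 0 <= int(self.grade) <= 4:
            raise ConfigurationError(f"grade {self.grade} outside 0-4")


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    provenance: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path, check_files: bool = True) -> "DatasetManifest":
        """Load a manifest; relative paths resolve against its directory."""
        path = Path(path)
        doc = json.loads(path.read_text())
        root = path.parent

        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            return str(p if p.is_absolute() else root / p)

        records = []
        for r in doc["records"]:
            rec = ManifestRecord(**r)
            rec.image = resolve(rec.image)
            rec.annotation = resolve(rec.annotation)
            if rec.masks:
                rec.masks = {k: resolve(v) for k, v in rec.masks.items()}
            records.append(rec)
        if check_files:
            for r in records:
                for p in [r.image, r.annotation, *(r.masks or {}).values()]:
                    if p is not None and not Path(p).exists():
                        raise InputContractError(f"manifest refers to missing file {p}")
        return cls(records=records, provenance=doc.get("provenance", {}))

    def save(self, path) -> None:
        doc = {"records": [dataclasses.asdict(r) for r in self.records],
               "provenance": self.provenance}
        Path(path).write_text(json.dumps(doc, indent=2))


def summarize_grade_counts(counts) -> dict:
    """Per-grade counts and display percentages from raw counts.

    ``counts`` is a sequence of five per-grade counts (grades 0-4) or a
    ``{grade: count}`` mapping.  Percentages are count/total * 100 rounded
    to 2 decimals for display.
    """
    if isinstance(counts, dict):
        seq = [int(counts.get(g, 0)) for g in range(5)]
    else:
        seq = [int(c) for c in counts]
        if len(seq) != 5:
            raise ConfigurationError("expected five per-grade counts")
    total = sum(seq)
    if total == 0:
        raise ConfigurationError("empty dataset summary")
    return {
        "total": total,
        "counts": dict(zip(range(5), seq)),
        "percent": {g: round(100.0 * c / total, 2) for g, c in zip(range(5), seq)},
        "names": dict(zip(range(5), GRADE_NAMES)),
    }


def summarize_manifest(manifest: DatasetManifest) -> dict:
    """Grade distribution of a manifest (counts and display percentages)."""
    if not manifest.records:
        raise ConfigurationError("empty manifest")
    counts = {g: 0 for g in range(5)}
    for r in manifest.records:
        counts[int(r.grade)] += 1
    return summarize_grade_counts(counts)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One pipeline run: methods, attribution knobs, metric settings, output.

    ``exclude_from_quality`` lists methods dropped from the averaged quality
    tables (default: the CAM pair, whose perturbation curves are too
    unstable to average); their per-image records are still written.
    """

    methods: tuple = ("deeplift", "gradient", "integrated_gradients", "shap",
                      "smoothgrad")
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    step: float = 0.02
    percentile: float = 0.9
    mask_value: float = 0.0
    cam_layer: str | None = None
    outdir: str = "results"
    seed: int = 0
    exclude_from_quality: tuple = CAM_METHODS

    def __post_init__(self):
        if not self.methods:
            raise ConfigurationError("method list is empty")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ConfigurationError(f"unknown methods {unknown}")
        if not 0 < self.step <= 1 or not 0 < self.percentile < 1:
            raise ConfigurationError("step/percentile out of range")
        # single-seed policy: the attribution RNG follows the run seed
        self.attribution = dataclasses.replace(self.attribution, rng_seed=self.seed)


def _plot_curve(curve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve.ratios * 100.0, curve.confidences)
    ax.set_xlabel("Perturbed Pixel Percentage (%)")
    ax.set_ylabel("Model Confidence for Target Class")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig, items, handle: ClassifierHandle,
                 plots: bool = True) -> dict:
    """Evaluate every manifest item with every configured method.

    ``items`` is a :class:`DatasetManifest` or an in-memory iterable of
    ``(image, label, mask_or_None)`` triples.  Writes saliency artifacts,
    perturbation-curve tables (and optionally plots), per-grade CSV quality
    tables, and a machine-readable JSON report.  Returns
    ``{"records": [...], "report": DataFrame, "paths": {...}}``.  Every
    input appears in the output as a result row or a recorded failure.
    """
    import pandas as pd

    outdir = Path(config.outdir)
    (outdir / "saliency").mkdir(parents=True, exist_ok=True)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)

    if isinstance(items, DatasetManifest):
        if not items.records:
            raise ConfigurationError("empty manifest")
        loaded = []
        for rec in items.records:
            image = load_image(rec.image, handle.spec)
            mask = None
            if rec.annotation:
                mask = load_annotations(rec.annotation,
                                        (handle.spec.height, handle.spec.width)
                                        ).union_for((handle.spec.height,
                                                     handle.spec.width))
            elif rec.masks:
                mask = np.zeros((handle.spec.height, handle.spec.width), bool)
                for p in rec.masks.values():
                    mask |= load_mask_png(p)
            loaded.append((image, rec.grade, mask))
        items = loaded
    else:
        items = list(items)

    logger.info("pipeline: %d items x %d methods, seed=%d",
                len(items), len(config.methods), config.seed)

    def hook(idx, rec, sal, curve):
        stem = outdir / "saliency" / f"item{idx:03d}_{rec.method}"
        save_saliency(sal, stem, meta={"label": rec.label, "seed": config.seed,
                                       "model": rec.model_id})
        cpath = outdir / "curves" / f"item{idx:03d}_{rec.method}.csv"
        pd.DataFrame({"ratio": curve.ratios,
                      "confidence": curve.confidences}).to_csv(cpath, index=False)
        if plots:
            _plot_curve(curve, cpath.with_suffix(".png"))

    records = evaluate_batch(
        handle, items, config.methods, config=config.attribution,
        step=config.step, percentile=config.percentile,
        mask_value=config.mask_value, cam_layer=config.cam_layer,
        saliency_hook=hook)

    report = summarize_records(records, exclude_methods=config.exclude_from_quality)
    paths = {}
    for label in sorted(report["Label"].unique()):
        sub = report[report["Label"] == label]
        p = outdir / f"quality_label{label}.csv"
        sub.to_csv(p, index=False, float_format="%.4f")
        paths[f"label{label}"] = str(p)

    json_doc = {
        "config": {
            "methods": list(config.methods),
            "step": config.step, "percentile": config.percentile,
            "mask_value": config.mask_value, "seed": config.seed,
            "excluded_from_quality": list(config.exclude_from_quality),
            "attribution": dataclasses.asdict(config.attribution)
            if not isinstance(config.attribution.baseline, np.ndarray) else "custom",
        },
        "records": [dataclasses.asdict(r) for r in records],
        "quality": report.to_dict(orient="records"),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(json_doc, indent=2))
    paths["report"] = str(report_path)
    failures = [r for r in records if r.error is not None]
    if failures:
        logger.warning("pipeline: %d row(s) failed", len(failures))
    return {"records": records, "report": report, "paths": paths}
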