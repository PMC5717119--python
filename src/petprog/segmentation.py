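"""Metabolic tumour volume delineation.

A bank of classical PET automatic segmentation (PET-AS) methods — fixed
percentage-of-maximum thresholding, two-class fuzzy c-means, region growing
from the hottest voxel, and iterative adaptive thresholding — plus a
trainable per-case method selector: every method is scored by Dice against
ground truth on a training suite of phantoms, and a shallow decision tree
learns which method to apply from simple case descriptors (estimated
tumour-to-background ratio, approximate volume at the 40% isocontour, and the
intensity coefficient of variation).  This mirrors the
decision-tree-selects-method architecture used to standardise tumour
delineation in the source workflow, retrained here on synthetic phantoms.

All masks are post-processed to their largest 26-connected component: a
single primary tumour is assumed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from sklearn.tree import DecisionTreeClassifier

from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    GeometryError,
    ValidationError,
)
from .io import BinaryMask, PETVolume, check_grid_congruence

#: Tie-break precedence when two methods score the same Dice (first wins).
METHOD_PRECEDENCE = (
    "adaptive_threshold",
    "fuzzy_cmeans",
    "threshold_percent_max",
    "region_grow",
)

SUV_MAX_ELIGIBILITY = 3.0  # SUV; below -> poorly FDG-avid, excluded
MTV_ELIGIBILITY_ML = 5.0  # ml; below -> too small for texture analysis


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive per-axis index ranges ((x0,x1),(y0,y1),(z0,z1))."""

    ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.ranges) != 3 or any(len(r) != 2 for r in self.ranges):
            raise ValidationError("bounding box needs 3 (lo, hi) index pairs")
        if any(hi < lo or lo < 0 for lo, hi in self.ranges):
            raise GeometryError(f"invalid bounding box ranges {self.ranges}")
        if self.n_voxels < 8:
            raise GeometryError(
                f"bounding box holds {self.n_voxels} voxels; minimum is 8"
            )

    @property
    def n_voxels(self) -> int:
        return int(np.prod([hi - lo + 1 for lo, hi in self.ranges]))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi + 1) for lo, hi in self.ranges)

    @classmethod
    def full_grid(cls, shape) -> "BoundingBox":
        return cls(tuple((0, int(n) - 1) for n in shape))

    @classmethod
    def around_mask(cls, mask: "BinaryMask", margin: int = 4) -> "BoundingBox":
        """A snug box around a mask's foreground, padded by ``margin`` voxels.

        Stands in for the manual bounding box a reader draws around the
        lesion before automatic segmentation."""
        if mask.n_foreground == 0:
            raise GeometryError("cannot box an empty mask")
        idx = np.nonzero(mask.voxels)
        ranges = tuple(
            (max(int(ax.min()) - margin, 0), min(int(ax.max()) + margin, n - 1))
            for ax, n in zip(idx, mask.shape)
        )
        return cls(ranges)


@dataclass(frozen=True)
class SegmentationResult:
    """A delineated tumour with its summary measures and QC flags."""

    mask: BinaryMask
    method: str
    mtv_ml: float
    suv_max: float
    qc_flags: tuple[str, ...] = ()


def crop(volume: PETVolume, box: BoundingBox) -> PETVolume:
    """Extract the sub-volume inside ``box``, adjusting the origin."""
    for (lo, hi), n in zip(box.ranges, volume.shape):
        if hi >= n:
            raise GeometryError(f"bounding box {box.ranges} outside grid {volume.shape}")
    sub = volume.voxels[box.slices]
    origin = tuple(
        o + lo * s
        for o, (lo, _), s in zip(volume.origin, box.ranges, volume.spacing)
    )
    return PETVolume(sub.copy(), volume.spacing, origin)


def _largest_component(fore: np.ndarray) -> np.ndarray:
    """Keep the largest 26-connected foreground component."""
    labels = measure.label(fore, connectivity=3)
    if labels.max() == 0:
        return fore
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _as_mask(fore: np.ndarray, volume: PETVolume) -> BinaryMask:
    return BinaryMask(fore.astype(np.uint8), volume.spacing, volume.origin)


def threshold_percent_max(volume: PETVolume, fraction: float) -> BinaryMask:
    """Voxels at or above ``fraction`` x SUVmax, largest component kept."""
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0,1), got {fraction}")
    v = volume.voxels
    if v.max() <= 0:
        raise DegenerateInputError("all-zero volume cannot be thresholded")
    fore = v >= fraction * v.max()
    return _as_mask(_largest_component(fore), volume)


def fuzzy_cmeans_2class(
    volume: PETVolume, max_iter: int = 300, tol: float = 1e-7
) -> BinaryMask:
    """Two-cluster fuzzy c-means (fuzzifier m=2) on voxel intensities.

    Centroids are initialised at (min, max), making the procedure
    deterministic.  The foreground is the higher-centroid cluster at
    membership > 0.5, reduced to its largest 26-connected component.
    """
    x = volume.voxels.ravel().astype(float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant volume: fuzzy c-means is undefined")
    c = np.array([x.min(), x.max()])
    for _ in range(max_iter):
        d2 = (x[:, None] - c[None, :]) ** 2
        d2 = np.maximum(d2, 1e-12)
        inv = 1.0 / d2
        u = inv / inv.sum(axis=1, keepdims=True)  # memberships, m = 2
        w = u**2
        c_new = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
        if np.max(np.abs(c_new - c)) < tol:
            c = c_new
            break
        c = c_new
    hot = int(np.argmax(c))
    fore = (u[:, hot] > 0.5).reshape(volume.shape)
    return _as_mask(_largest_component(fore), volume)


def region_grow(volume: PETVolume, fraction: float = 0.5) -> BinaryMask:
    """Grow from the SUVmax voxel over 26-neighbours >= fraction x SUVmax."""
    v = volume.voxels
    if v.max() <= 0:
        raise DegenerateInputError("all-zero volume cannot seed region growing")
    seed = np.unravel_index(int(np.argmax(v)), v.shape)
    candidate = v >= fraction * v.max()
    labels = measure.label(candidate, connectivity=3)
    fore = labels == labels[seed]
    return _as_mask(fore, volume)


def adaptive_threshold(
    volume: PETVolume, beta: float = 0.5, max_iter: int = 100
) -> BinaryMask:
    """Iterative background-adapted thresholding.

    ``peak_mean`` is the mean SUV of the hottest region (voxels within 90% of
    SUVmax); the threshold iterates ``T <- bg_mean + beta * (peak_mean -
    bg_mean)`` with the background mean re-estimated outside the current mask,
    until the mask reaches a fixed point.  Anchoring on the peak region keeps
    the threshold from drifting into the background as the mask grows.
    """
    v = volume.voxels
    if np.ptp(v) == 0:
        raise DegenerateInputError("constant volume: adaptive threshold is undefined")
    peak_mean = v[v >= 0.9 * v.max()].mean()
    t = 0.5 * v.max()
    thresholds = [t]
    mask = v >= t
    for _ in range(max_iter):
        outside = v[~mask]
        if outside.size == 0 or not mask.any():
            break
        bg = outside.mean()
        t = bg + beta * (peak_mean - bg)
        thresholds.append(float(t))
        new_mask = v >= t
        if np.array_equal(new_mask, mask):
            return _as_mask(_largest_component(mask), volume)
        mask = new_mask
    else:
        raise ConvergenceError(
            "adaptive threshold did not reach a fixed point in "
            f"{max_iter} iterations; last thresholds {thresholds[-2]:.4f}, "
            f"{thresholds[-1]:.4f}"
        )
    return _as_mask(_largest_component(mask), volume)


METHODS = {
    "threshold_percent_max": lambda v: threshold_percent_max(v, 0.4),
    "fuzzy_cmeans": fuzzy_cmeans_2class,
    "region_grow": region_grow,
    "adaptive_threshold": adaptive_threshold,
}


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    av = a.voxels if isinstance(a, BinaryMask) else np.asarray(a, bool)
    bv = b.voxels if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)


def case_features(volume: PETVolume) -> np.ndarray:
    """Descriptors used by the method selector.

    [TBR estimate (mean inside 40% isocontour / mean outside),
     approximate volume (ml) at the 40% isocontour,
     coefficient of variation of the box intensities]
    """
    v = volume.voxels
    fore = v >= 0.4 * v.max()
    inside = v[fore]
    outside = v[~fore]
    bg = outside.mean() if outside.size else 0.0
    # cap keeps the feature finite when the isocontour fills the box
    tbr = min(inside.mean() / bg, 1e3) if bg > 0 else 1e3
    vol_ml = fore.sum() * volume.voxel_volume_ml
    cv = v.std() / v.mean() if v.mean() > 0 else 0.0
    return np.array([tbr, vol_ml, cv], dtype=float)


@dataclass(frozen=True)
class MethodSelector:
    """A shallow decision tree mapping case descriptors to a PET-AS method.

    Stored as plain arrays (children, split feature, threshold, leaf method)
    so a trained selector round-trips through a small JSON file.
    """

    children_left: tuple[int, ...]
    children_right: tuple[int, ...]
    feature: tuple[int, ...]
    threshold: tuple[float, ...]
    node_method: tuple[str, ...]

    def predict(self, features: np.ndarray) -> str:
        node = 0
        f = np.asarray(features, float)
        while self.children_left[node] != -1:
            if f[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return self.node_method[node]

    def save(self, path) -> None:
        payload = {
            "format": "petprog-method-selector-v1",
            "features": ["tbr_estimate", "volume40_ml", "intensity_cv"],
            "children_left": list(self.children_left),
            "children_right": list(self.children_right),
            "feature": list(self.feature),
            "threshold": list(self.threshold),
            "node_method": list(self.node_method),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "MethodSelector":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["children_left"]),
            tuple(payload["children_right"]),
            tuple(payload["feature"]),
            tuple(payload["threshold"]),
            tuple(payload["node_method"]),
        )


def _best_method(scores: dict[str, float]) -> str:
    best = max(scores.values())
    for name in METHOD_PRECEDENCE:
        if name in scores and scores[name] == best:
            return name
    raise RuntimeError("unreachable: no method scored")  # pragma: no cover


def score_methods(volume: PETVolume, truth: BinaryMask) -> dict[str, float]:
    """Dice of every bank method against ground truth (errors score 0)."""
    out = {}
    for name, fn in METHODS.items():
        try:
            out[name] = dice(fn(volume), truth)
        except (DegenerateInputError, ConvergenceError):
            out[name] = 0.0
    return out


def train_selector(
    phantoms: list[tuple[PETVolume, BinaryMask]], max_depth: int = 3
) -> MethodSelector:
    """Fit the method selector on (volume, ground-truth mask) training pairs.

    Each phantom is segmented with every bank method; the Dice-best method
    (ties broken by :data:`METHOD_PRECEDENCE`) becomes the training label for
    a depth-limited decision tree over :func:`case_features`.  Cases are
    weighted by the regret margin (best Dice minus the mean of the other
    methods): a phantom on which all methods tie carries no routing
    information, while one where a wrong pick collapses the mask dominates.
    """
    if len(phantoms) < 20:
        raise ValidationError(
            f"selector training needs >= 20 phantoms, got {len(phantoms)}"
        )
    x = np.array([case_features(v) for v, _ in phantoms])
    scores = [score_methods(v, m) for v, m in phantoms]
    y = np.array([_best_method(s) for s in scores])
    weight = np.array(
        [max(s.values()) - (sum(s.values()) - max(s.values())) / (len(s) - 1)
         for s in scores]
    ) + 1e-3
    if len(set(y)) == 1:
        warnings.warn(
            f"all training phantoms favour {y[0]!r}; selector is constant",
            stacklevel=2,
        )
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=0).fit(
        x, y, sample_weight=weight
    )
    t = tree.tree_
    node_method = tuple(
        str(tree.classes_[int(np.argmax(t.value[i]))]) for i in range(t.node_count)
    )
    return MethodSelector(
        tuple(int(i) for i in t.children_left),
        tuple(int(i) for i in t.children_right),
        tuple(int(i) for i in t.feature),
        tuple(float(v) for v in t.threshold),
        node_method,
    )


def select_and_segment(
    volume: PETVolume, box: BoundingBox, selector: MethodSelector
) -> SegmentationResult:
    """Crop to the box, pick a method with the selector, and segment.

    The returned mask lives on the full input grid; QC flags note masks that
    touch the box boundary or fill an implausible share of the box.
    """
    sub = crop(volume, box)
    method = selector.predict(case_features(sub))
    sub_mask = METHODS[method](sub)

    full = np.zeros(volume.shape, dtype=np.uint8)
    full[box.slices] = sub_mask.voxels
    mask = BinaryMask(full, volume.spacing, volume.origin)

    flags = []
    inner = sub_mask.voxels
    boundary = np.zeros_like(inner)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    if np.logical_and(inner, boundary).any():
        flags.append("mask_touches_box_boundary")
    if inner.sum() > 0.9 * inner.size:
        flags.append("mask_fills_box")

    suv_max = float(volume.voxels[mask.voxels].max()) if mask.n_foreground else 0.0
    return SegmentationResult(
        mask=mask,
        method=method,
        mtv_ml=mask.volume_ml,
        suv_max=suv_max,
        qc_flags=tuple(flags),
    )


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: str | None = None


def eligibility_filter(result: SegmentationResult) -> Eligibility:
    """Apply the cohort exclusion rules (strict '<' thresholds).

    Poorly FDG-avid tumours (SUVmax < 3) are excluded first, then tumours too
    small for stable texture analysis (MTV < 5 ml).
    """
    if result.suv_max < SUV_MAX_ELIGIBILITY:
        return Eligibility(False, "low_avidity")
    if result.mtv_ml < MTV_ELIGIBILITY_ML:
        return Eligibility(False, "small_volume")
    return Eligibility(True, None)
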