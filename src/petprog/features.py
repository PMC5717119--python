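"""The 16 PET metrics computed from a volume + tumour mask pair.

Intensity metrics (SUVmax, SUVmean, MTV, TLG) and the histogram shape moments
are computed on raw SUVs; all matrix-based texture metrics (GLCM, NGTDM
coarseness, GLSZM) operate on a fixed-bin-width discretisation anchored at
SUV 0 with 0.5-SUV bins, i.e. bin i covers [(i-1)*w, i*w).  Conventions that
the metric definitions leave open are fixed as follows and are configurable
where noted:

* entropies use log base 2 (bits);
* the GLCM is a single symmetric matrix accumulated over the 13 unique 3D
  direction offsets at Chebyshev distance 1, counting only voxel pairs that
  both lie inside the mask;
* zone and neighbourhood connectivity is 26 (3D Chebyshev);
* NGTDM coarseness uses epsilon = 1e-6 to cap the constant-region case.

Histogram moments use the population divisor N, and kurtosis is non-excess
(a Gaussian scores 3, and no distribution scores below 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .exceptions import DegenerateInputError
from .io import FEATURE_COLUMNS, BinaryMask, PETVolume, check_grid_congruence

NGTDM_EPSILON = 1e-6

#: The 13 unique 3D direction offsets at Chebyshev distance 1.
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class DiscretisedROI:
    """A masked ROI with raw SUVs and their fixed-bin-width quantisation."""

    bin_grid: np.ndarray  # 3D int array, 1-based bins inside mask, 0 outside
    mask: np.ndarray  # 3D bool
    raw_values: np.ndarray  # 1D float, ROI voxels in C order
    bins: np.ndarray  # 1D int, parallel to raw_values
    bin_width: float
    voxel_volume_ml: float

    @property
    def n(self) -> int:
        return self.raw_values.size


def discretise(
    volume: PETVolume, mask: BinaryMask, bin_width: float = 0.5
) -> DiscretisedROI:
    """Quantise the masked SUVs into fixed-width bins anchored at SUV 0.

    ``bin(v) = floor(v / width) + 1``; a voxel at exactly a bin edge belongs
    to the upper bin (half-open intervals).
    """
    check_grid_congruence(volume, mask)
    m = mask.voxels
    if not m.any():
        raise DegenerateInputError("empty mask: nothing to discretise")
    if bin_width <= 0:
        raise DegenerateInputError(f"bin width must be > 0, got {bin_width}")
    raw = volume.voxels[m]
    bins_flat = np.floor(raw / bin_width).astype(np.int64) + 1
    bin_grid = np.zeros(volume.shape, dtype=np.int64)
    bin_grid[m] = bins_flat
    return DiscretisedROI(
        bin_grid=bin_grid,
        mask=m,
        raw_values=raw.astype(float),
        bins=bins_flat,
        bin_width=float(bin_width),
        voxel_volume_ml=volume.voxel_volume_ml,
    )


def histogram_distribution(roi: DiscretisedROI) -> tuple[np.ndarray, np.ndarray]:
    """Occupied bin levels and their probabilities P(i) = N_i / N."""
    levels, counts = np.unique(roi.bins, return_counts=True)
    return levels, counts / roi.n


def suv_stats(roi: DiscretisedROI) -> dict[str, float]:
    """SUVmax, SUVmean, MTV (ml) and TLG = SUVmean x MTV, from raw SUVs."""
    raw = roi.raw_values
    mtv = roi.n * roi.voxel_volume_ml
    suv_mean = float(raw.mean())
    return {
        "suv_max": float(raw.max()),
        "suv_mean": suv_mean,
        "mtv_ml": mtv,
        "tlg": suv_mean * mtv,
    }


def histogram_features(roi: DiscretisedROI) -> dict[str, float]:
    """First-order metrics: SD, entropy, energy, skewness, kurtosis.

    Energy = sum_i P(i)^2 and entropy = -sum_i P(i) log2 P(i) use the binned
    distribution; SD, skewness and kurtosis are population moments of the raw
    SUVs.  A constant ROI has no defined skewness/kurtosis and raises
    :class:`DegenerateInputError`.
    """
    _, p = histogram_distribution(roi)
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(p * np.log2(p)))

    raw = roi.raw_values
    if roi.n < 2:
        raise DegenerateInputError("histogram shape metrics need N >= 2")
    mu = raw.mean()
    var = float(np.mean((raw - mu) ** 2))  # population divisor N
    sd = math.sqrt(var)
    if var == 0:
        raise DegenerateInputError(
            "constant ROI: skewness and kurtosis are undefined"
        )
    skew = float(np.mean((raw - mu) ** 3) / var**1.5)
    kurt = float(np.mean((raw - mu) ** 4) / var**2)  # non-excess
    return {
        "hist_sd": sd,
        "hist_entropy": entropy,
        "hist_energy": energy,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
    }


def glcm_matrix(roi: DiscretisedROI) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric co-occurrence probabilities over the 13 unique offsets.

    Returns ``(levels, p)`` where ``p[i, j]`` is the probability of the
    ordered pair (levels[i], levels[j]); both orders of every in-mask
    neighbour pair are counted, so ``p`` is symmetric.
    """
    levels = np.unique(roi.bins)
    index = np.full(int(levels.max()) + 1, -1, dtype=np.int64)
    index[levels] = np.arange(levels.size)
    g = levels.size
    counts = np.zeros((g, g), dtype=np.int64)
    bins, m = roi.bin_grid, roi.mask

    def shifted(arr, off, side):
        sl = []
        for d in off:
            if side == 0:
                sl.append(slice(None, -d or None) if d >= 0 else slice(-d, None))
            else:
                sl.append(slice(d, None) if d >= 0 else slice(None, d))
        return arr[tuple(sl)]

    for off in GLCM_OFFSETS:
        ma = shifted(m, off, 0) & shifted(m, off, 1)
        if not ma.any():
            continue
        a = index[shifted(bins, off, 0)[ma]]
        b = index[shifted(bins, off, 1)[ma]]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError("no in-mask neighbour pair for the GLCM")
    return levels, counts / total


def glcm_features(roi: DiscretisedROI) -> dict[str, float]:
    """GLCM homogeneity, entropy (bits) and dissimilarity."""
    levels, p = glcm_matrix(roi)
    d = np.abs(levels[:, None] - levels[None, :]).astype(float)
    nz = p > 0
    return {
        "glcm_homogeneity": float(np.sum(p / (1.0 + d))),
        "glcm_entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "glcm_dissimilarity": float(np.sum(p * d)),
    }


def ngtdm_coarseness(roi: DiscretisedROI) -> float:
    """Neighbourhood grey-tone difference coarseness.

    For every ROI voxel with at least one in-mask 26-neighbour, the absolute
    difference between its bin and the mean bin of those neighbours is
    accumulated per bin level (s_i); with occupancy fractions p_i over the
    contributing voxels, coarseness = 1 / (epsilon + sum_i p_i * s_i).
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    m = roi.mask.astype(float)
    n_nb = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    s_nb = ndimage.convolve(roi.bin_grid * m, kernel, mode="constant", cval=0.0)
    valid = roi.mask & (n_nb > 0.5)
    if not valid.any():
        raise DegenerateInputError("no ROI voxel has an in-mask neighbour")
    a = s_nb[valid] / n_nb[valid]
    b = roi.bin_grid[valid].astype(float)
    diff = np.abs(b - a)
    n_valid = int(valid.sum())
    levels = np.unique(roi.bin_grid[valid])
    total = 0.0
    for lv in levels:
        sel = b == lv
        p_i = sel.sum() / n_valid
        s_i = diff[sel].sum()
        total += p_i * s_i
    return float(1.0 / (NGTDM_EPSILON + total))


def glszm(roi: DiscretisedROI) -> list[tuple[int, int]]:
    """Zones as (bin level, size) pairs; 26-connected equal-bin regions."""
    zones = []
    for lv in np.unique(roi.bins):
        lab = measure.label((roi.bin_grid == lv) & roi.mask, connectivity=3)
        if lab.max() == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(lv), int(s)) for s in sizes if s > 0)
    return zones


def glszm_features(roi: DiscretisedROI) -> dict[str, float]:
    """GLSZM intensity variability, large-area emphasis, zone percentage."""
    zones = glszm(roi)
    n_z = len(zones)
    levels = np.array([z[0] for z in zones])
    sizes = np.array([z[1] for z in zones], dtype=float)
    zones_per_level = np.unique(levels, return_counts=True)[1].astype(float)
    return {
        "glszm_intensity_variability": float(np.sum(zones_per_level**2) / n_z),
        "glszm_large_area_emphasis": float(np.sum(sizes**2) / n_z),
        "glszm_zone_percentage": n_z / roi.n,
    }


@dataclass(frozen=True)
class FeatureVector:
    """The 16 PET metrics for one case; degenerate metrics are NaN with a
    recorded reason in ``missing``."""

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_row(self) -> dict[str, float]:
        return {name: self.values.get(name, float("nan")) for name in FEATURE_COLUMNS}


def extract_all(
    volume: PETVolume, mask: BinaryMask, bin_width: float = 0.5
) -> FeatureVector:
    """Compute the full 16-metric vector; degeneracies become flagged NaNs."""
    roi = discretise(volume, mask, bin_width)
    values: dict[str, float] = {}
    missing: dict[str, str] = {}

    values.update(suv_stats(roi))

    try:
        values.update(histogram_features(roi))
    except DegenerateInputError as exc:
        # energy/entropy/SD remain defined for a constant ROI
        _, p = histogram_distribution(roi)
        values["hist_energy"] = float(np.sum(p**2))
        values["hist_entropy"] = float(-np.sum(p * np.log2(p)))
        values["hist_sd"] = float(roi.raw_values.std())
        for name in ("hist_skewness", "hist_kurtosis"):
            values[name] = float("nan")
            missing[name] = str(exc)

    try:
        values.update(glcm_features(roi))
    except DegenerateInputError as exc:
        for name in ("glcm_homogeneity", "glcm_entropy", "glcm_dissimilarity"):
            values[name] = float("nan")
            missing[name] = str(exc)

    try:
        values["ngtdm_coarseness"] = ngtdm_coarseness(roi)
    except DegenerateInputError as exc:
        values["ngtdm_coarseness"] = float("nan")
        missing["ngtdm_coarseness"] = str(exc)

    values.update(glszm_features(roi))
    return FeatureVector(values=values, missing=missing)
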