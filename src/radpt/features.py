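"""The 2D texture battery: 150 features per sequence per ROI.

Default composition per sequence per ROI (all parameters configurable):

====================  =====
signal intensity          1
first-order (3x3/5x5)     9
Gabor (4 wavelengths
  x 19 orientations)     76
Haralick (3 windows
  x 13 statistics)       39
Laws energy (5x5)        25
====================  =====

All operators produce pixel-wise response maps; features are the maps
aggregated over a ROI (default aggregator: mean; sd / skewness /
kurtosis optional).  Multi-slice ROIs pool pixels across slices before
aggregation.  A CoLlAGe extension set (13 gradient-orientation
co-occurrence statistics) is available but off by default so the
printed 150/300/1200 column contract holds.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from radpt.rings import ROI_NAMES

logger = logging.getLogger(__name__)

SEQUENCES = ("T2W", "ADC")
AGGREGATORS = ("mean", "sd", "skewness", "kurtosis")

HARALICK_STATS = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_1",
    "info_measure_2",
)

FIRST_ORDER_MAPS = (
    "mean3", "median3", "sd3", "range3",
    "sobel_x", "sobel_y", "sobel_mag",
    "mean5", "median5",
)

# the four distance-1 co-occurrence directions
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


# ---------------------------------------------------------------------------
# configuration and feature naming
# ---------------------------------------------------------------------------

@dataclass
class BatteryConfig:
    gabor_wavelengths: tuple = (3.0, 4.0, 5.0, 6.0)
    gabor_n_orientations: int = 19
    haralick_windows: tuple = (3, 5, 7)
    n_levels: int = 64
    include_collage: bool = False
    collage_window: int = 5
    collage_angle_bins: int = 64
    aggregators: tuple = ("mean",)
    allow_any_bank: bool = False

    def __post_init__(self) -> None:
        if any(w % 2 == 0 or w < 3 for w in self.haralick_windows):
            raise ValueError("haralick windows must be odd and >= 3")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        n_bank = len(self.gabor_wavelengths) * self.gabor_n_orientations
        if n_bank != 76 and not self.allow_any_bank:
            raise ValueError(
                f"gabor bank size {n_bank} != 76; pass allow_any_bank=True "
                "to deviate from the default battery"
            )
        bad = set(self.aggregators) - set(AGGREGATORS)
        if bad:
            raise ValueError(f"unknown aggregators: {sorted(bad)}")

    def gabor_thetas(self) -> np.ndarray:
        return np.arange(self.gabor_n_orientations) * np.pi / self.gabor_n_orientations


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: operator + parameters + sequence + ROI + aggregator."""

    family: str
    params: tuple  # sorted (key, value) pairs
    sequence: str
    roi: str
    aggregator: str = "mean"

    @property
    def name(self) -> str:
        par = ",".join(f"{k}={_fmt(v)}" for k, v in self.params)
        return f"{self.family}({par})|{self.sequence}|{self.roi}|{self.aggregator}"

    @classmethod
    def from_name(cls, name: str) -> "FeatureSpec":
        m = re.fullmatch(r"(\w+)\(([^)]*)\)\|(\w+)\|(\w+)\|(\w+)", name)
        if not m:
            raise ValueError(f"unparseable feature name {name!r}")
        family, par, sequence, roi, agg = m.groups()
        params = []
        if par:
            for item in par.split(","):
                k, v = item.split("=")
                try:
                    params.append((k, int(v)))
                except ValueError:
                    try:
                        params.append((k, float(v)))
                    except ValueError:
                        params.append((k, v))
        return cls(family, tuple(params), sequence, roi, agg)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def battery_map_ids(config: BatteryConfig) -> list[tuple[str, tuple]]:
    """Ordered (family, params) pairs of the per-sequence-per-ROI battery."""
    ids: list[tuple[str, tuple]] = [("signal", ())]
    ids += [("first_order", (("stat", s),)) for s in FIRST_ORDER_MAPS]
    for lam in config.gabor_wavelengths:
        for th in config.gabor_thetas():
            ids.append(("gabor", (("lam", float(lam)), ("theta", round(float(th), 4)))))
    for w in config.haralick_windows:
        for s in HARALICK_STATS:
            ids.append(("haralick", (("stat", s), ("win", int(w)))))
    for name in laws_kernel_names():
        ids.append(("laws", (("kernel", name),)))
    if config.include_collage:
        for s in HARALICK_STATS:
            ids.append(("collage", (("stat", s), ("win", int(config.collage_window)))))
    return ids


def battery_specs(config: BatteryConfig | None = None,
                  sequences=SEQUENCES, rois=ROI_NAMES) -> list[FeatureSpec]:
    """Full enumeration of FeatureSpecs (sequence x ROI x map x aggregator)."""
    config = config or BatteryConfig()
    ids = battery_map_ids(config)
    specs = []
    for seq in sequences:
        for roi in rois:
            for fam, params in ids:
                for agg in config.aggregators:
                    specs.append(FeatureSpec(fam, params, seq, roi, agg))
    return specs


# ---------------------------------------------------------------------------
# quantization and co-occurrence
# ---------------------------------------------------------------------------

def quantize(image: np.ndarray, roi_mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization between the within-ROI min and max.

    Returns integer levels in ``0..n_levels-1`` over the whole grid
    (values outside the ROI range are clipped); a constant ROI maps to
    level 0 everywhere.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    image = np.asarray(image, dtype=float)
    lo = image[roi_mask].min()
    hi = image[roi_mask].max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(q, 0, n_levels - 1)


def glcm(quantized: np.ndarray, offsets=GLCM_OFFSETS, symmetric: bool = True,
         n_levels: int | None = None) -> np.ndarray:
    """Normalised gray-level co-occurrence matrix of a quantized window."""
    q = np.asarray(quantized)
    if q.size == 0:
        raise ValueError("window is empty")
    if not offsets:
        raise ValueError("offsets are empty")
    L = int(n_levels if n_levels is not None else q.max() + 1)
    mat = np.zeros((L, L), dtype=float)
    h, w = q.shape
    n_pairs = 0
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), h - max(0, dy)
        x0, x1 = max(0, -dx), w - max(0, dx)
        if y1 <= y0 or x1 <= x0:
            continue
        a = q[y0:y1, x0:x1].ravel()
        b = q[y0 + dy:y1 + dy, x0 + dx:x1 + dx].ravel()
        np.add.at(mat, (a, b), 1.0)
        n_pairs += a.size
    if n_pairs == 0:
        raise ValueError("window smaller than offset reach: no pixel pairs")
    if symmetric:
        mat = mat + mat.T
    return mat / mat.sum()


def _ent_rows(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=-1)


def _haralick_batch(P: np.ndarray) -> np.ndarray:
    """13 Haralick statistics for a batch of GLCMs (B, L, L).

    Input matrices may be counts or probabilities (each is normalised by
    its own total); zero-total matrices give NaN rows.
    """
    P = np.asarray(P)
    B, L, _ = P.shape
    rows, ci, cj = P.nonzero()
    return _haralick_sparse(rows, ci, cj, P[rows, ci, cj].astype(float), B, L)


def _haralick_sparse(rows, ci, cj, weights, B: int, L: int) -> np.ndarray:
    """Haralick statistics from the sparse nonzero GLCM cells.

    ``rows`` indexes the matrix in the batch, ``(ci, cj)`` the cell and
    ``weights`` its (unnormalised) mass; window GLCMs are very sparse so
    all accumulation is O(nnz).
    """
    tot = np.bincount(rows, weights=weights, minlength=B)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = weights / tot[rows]
    ci = ci.astype(float)
    cj = cj.astype(float)
    rowsL = rows * L

    def _acc(weights, minlength=B):
        return np.bincount(rows, weights=weights, minlength=minlength)

    d = ci - cj
    energy = _acc(v * v)
    entropy = -_acc(v * np.log(v))
    contrast = _acc(v * d * d)
    idm = _acc(v / (1.0 + d * d))
    cross = _acc(v * ci * cj)

    px = np.bincount(rowsL + ci.astype(int), weights=v,
                     minlength=B * L).reshape(B, L)
    py = np.bincount(rowsL + cj.astype(int), weights=v,
                     minlength=B * L).reshape(B, L)
    psum = np.bincount(rows * (2 * L - 1) + (ci + cj).astype(int), weights=v,
                       minlength=B * (2 * L - 1)).reshape(B, 2 * L - 1)
    pdiff = np.bincount(rowsL + np.abs(d).astype(int), weights=v,
                        minlength=B * L).reshape(B, L)

    iv = np.arange(L, dtype=float)
    ks = np.arange(2 * L - 1, dtype=float)
    mux = px @ iv
    muy = py @ iv
    sx2 = px @ (iv**2) - mux**2
    sy2 = py @ (iv**2) - muy**2
    denom = np.sqrt(np.clip(sx2 * sy2, 0, None))
    correlation = np.where(denom > 1e-30,
                           (cross - mux * muy) / np.where(denom > 0, denom, 1),
                           0.0)
    variance = sx2  # sum-of-squares variance of the (symmetric) marginal
    sum_average = psum @ ks
    sum_variance = psum @ (ks**2) - sum_average**2
    sum_entropy = _ent_rows(psum)
    diff_avg = pdiff @ iv
    difference_variance = pdiff @ (iv**2) - diff_avg**2
    difference_entropy = _ent_rows(pdiff)
    hx = _ent_rows(px)
    hy = _ent_rows(py)
    hmax = np.maximum(hx, hy)
    info1 = np.where(hmax > 1e-30,
                     (entropy - hx - hy) / np.where(hmax > 0, hmax, 1), 0.0)
    info2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hx + hy - entropy)), 0.0, None))

    out = np.stack([
        energy, contrast, correlation, variance, idm,
        sum_average, sum_variance, sum_entropy, entropy,
        difference_variance, difference_entropy, info1, info2,
    ], axis=1)
    out[tot <= 0] = np.nan
    return out


def haralick_stats(glcm_matrix: np.ndarray) -> dict[str, float]:
    """The 13 named Haralick statistics of one normalised GLCM."""
    vals = _haralick_batch(np.asarray(glcm_matrix, dtype=float)[None])
    return dict(zip(HARALICK_STATS, vals[0]))


def _cooc_stat_maps(levels: np.ndarray, mask: np.ndarray, window: int,
                    n_levels: int, batch: int = 512) -> np.ndarray:
    """13 co-occurrence statistic maps over centred windows at mask pixels.

    ``levels`` holds integer levels in ``0..n_levels-1`` over the whole
    2D grid; windows are clipped at image borders and at the ROI: only
    pixel pairs with both endpoints inside the mask are counted, so a
    ROI's co-occurrence statistics never read intensities of another
    region.  Returns an array of shape ``(13, H, W)`` that is NaN
    outside the mask (and at mask pixels with no valid pair).
    """
    L = int(n_levels)
    pad = window // 2 + 1  # +1 sentinel margin for offset reach
    mask_arr = np.asarray(mask, dtype=bool)
    q = np.pad(np.where(mask_arr, levels, L), pad, constant_values=L)
    ncode = (L + 1) * (L + 1)

    # per-offset pair-code image over the padded grid
    code_imgs = []
    rel_lists = []
    H, W = q.shape
    half = window // 2
    for dy, dx in GLCM_OFFSETS:
        C = np.full(q.shape, ncode, dtype=np.int64)
        y0, y1 = max(0, -dy), H - max(0, dy)
        x0, x1 = max(0, -dx), W - max(0, dx)
        C[y0:y1, x0:x1] = q[y0:y1, x0:x1] * (L + 1) + q[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
        # start positions (relative to the centre) whose pair stays in-window
        rr = np.arange(-half + max(0, -dy), half - max(0, dy) + 1)
        cc = np.arange(-half + max(0, -dx), half - max(0, dx) + 1)
        rel = np.stack(np.meshgrid(rr, cc, indexing="ij"), -1).reshape(-1, 2)
        code_imgs.append(C)
        rel_lists.append(rel)

    ys, xs = np.nonzero(mask_arr)
    out = np.full((13,) + levels.shape, np.nan)
    if ys.size == 0:
        return out

    for s in range(0, ys.size, batch):
        py = ys[s:s + batch] + pad
        px = xs[s:s + batch] + pad
        B = py.size
        chunks = []
        for C, rel in zip(code_imgs, rel_lists):
            cy = py[:, None] + rel[None, :, 0]
            cx = px[:, None] + rel[None, :, 1]
            chunks.append(C[cy, cx])
        codes = np.concatenate(chunks, axis=1)
        a, b = codes // (L + 1), codes % (L + 1)
        invalid = (codes >= ncode) | (a == L) | (b == L)
        codes = np.where(invalid, ncode, codes)
        swapped = np.where(invalid, ncode, b * (L + 1) + a)  # symmetric GLCM
        both = np.concatenate([codes, swapped], axis=1)
        # run-length encode the sorted per-pixel code lists (sparse GLCMs)
        g = np.sort(both + (np.arange(B) * (ncode + 1))[:, None], axis=1).ravel()
        starts = np.concatenate([[0], np.flatnonzero(np.diff(g)) + 1])
        lens = np.diff(np.append(starts, g.size)).astype(float)
        vals = g[starts]
        rows = vals // (ncode + 1)
        cell = vals % (ncode + 1)
        keep = cell < ncode
        stats = _haralick_sparse(rows[keep], cell[keep] // (L + 1),
                                 cell[keep] % (L + 1), lens[keep], B, L)
        out[:, ys[s:s + B], xs[s:s + B]] = stats.T
    return out


def haralick_maps(image: np.ndarray, mask: np.ndarray,
                  window_sizes=(3, 5, 7), n_levels: int = 64) -> dict[str, np.ndarray]:
    """Per-pixel Haralick statistic maps for each window size.

    The image is quantized once with the within-mask min-max; each mask
    pixel then gets the 13 statistics of the symmetric GLCM accumulated
    over the 4 distance-1 directions inside the centred window, counting
    only pairs that lie entirely inside the mask (windows are clipped at
    image borders and at the ROI).  Keys are ``"{stat}_w{window}"``.
    """
    if any(w % 2 == 0 for w in window_sizes):
        raise ValueError("window sizes must be odd")
    q = quantize(image, mask, n_levels)
    out = {}
    for w in window_sizes:
        maps = _cooc_stat_maps(q, mask, w, n_levels)
        for idx, stat in enumerate(HARALICK_STATS):
            out[f"{stat}_w{w}"] = maps[idx]
    return out


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

def gabor_kernel(wavelength: float, theta: float,
                 sigma_factor: float = 0.5) -> np.ndarray:
    """Real-part Gabor kernel, DC-subtracted (zero mean), unit L2 norm."""
    sigma = sigma_factor * wavelength
    half = int(np.ceil(2.5 * sigma))
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    k = np.exp(-(xr**2 + yr**2) / (2 * sigma**2)) * np.cos(2 * np.pi * xr / wavelength)
    k -= k.mean()
    return k / np.linalg.norm(k)


def gabor_bank(config: BatteryConfig | None = None) -> list[tuple[tuple, np.ndarray]]:
    """The battery's Gabor bank: ((wavelength, theta), kernel) pairs."""
    config = config or BatteryConfig()
    bank = []
    for lam in config.gabor_wavelengths:
        for th in config.gabor_thetas():
            bank.append(((float(lam), float(th)), gabor_kernel(lam, th)))
    return bank


def _correlate2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    hy, hx = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((hy, hy), (hx, hx)), mode="reflect")
    return signal.fftconvolve(padded, kernel[::-1, ::-1], mode="valid")


def gabor_maps(image: np.ndarray, bank=None) -> list[tuple[tuple, np.ndarray]]:
    """Same-size filter responses (reflect-padded borders) for each kernel."""
    if bank is None:
        bank = gabor_bank()
    image = np.asarray(image, dtype=float)
    out = []
    for params, kernel in bank:
        if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
            raise ValueError("image smaller than Gabor kernel")
        out.append((params, _correlate2d_reflect(image, kernel)))
    return out


# ---------------------------------------------------------------------------
# Laws
# ---------------------------------------------------------------------------

_LAWS_1D = {
    "L5": np.array([1.0, 4, 6, 4, 1]),
    "E5": np.array([-1.0, -2, 0, 2, 1]),
    "S5": np.array([-1.0, 0, 2, 0, -1]),
    "W5": np.array([-1.0, 2, 0, -2, 1]),
    "R5": np.array([1.0, -4, 6, -4, 1]),
}
_LAWS_ORDER = ("L5", "E5", "S5", "W5", "R5")


def laws_kernel_names() -> list[str]:
    return [a + b for a in _LAWS_ORDER for b in _LAWS_ORDER]


def laws_kernels() -> dict[str, np.ndarray]:
    """The 25 separable 5x5 kernels from outer products of L5/E5/S5/W5/R5."""
    return {
        a + b: np.outer(_LAWS_1D[a], _LAWS_1D[b])
        for a in _LAWS_ORDER for b in _LAWS_ORDER
    }


def laws_maps(image: np.ndarray) -> dict[str, np.ndarray]:
    """25 Laws response maps (separable correlation, reflect padding)."""
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 5 or image.shape[1] < 5:
        raise ValueError("image must be at least 5x5")
    out = {}
    for a in _LAWS_ORDER:
        rowpass = ndimage.correlate1d(image, _LAWS_1D[a], axis=0, mode="reflect")
        for b in _LAWS_ORDER:
            out[a + b] = ndimage.correlate1d(rowpass, _LAWS_1D[b], axis=1,
                                             mode="reflect")
    return out


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def first_order_maps(image: np.ndarray, mask: np.ndarray):
    """Nine windowed first-order maps plus the within-ROI signal mean.

    Maps: 3x3 mean/median/SD/range, Sobel-x, Sobel-y, Sobel magnitude,
    5x5 mean and median (reflect padding throughout).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    maps = {}
    maps["mean3"] = ndimage.uniform_filter(image, 3, mode="reflect")
    maps["median3"] = ndimage.median_filter(image, 3, mode="reflect")
    # centre first: the windowed SD is shift-invariant and this avoids
    # catastrophic cancellation on near-constant images
    c = image - image.mean()
    m1 = ndimage.uniform_filter(c, 3, mode="reflect")
    m2 = ndimage.uniform_filter(c**2, 3, mode="reflect")
    maps["sd3"] = np.sqrt(np.clip(m2 - m1**2, 0, None))
    maps["range3"] = (ndimage.maximum_filter(image, 3, mode="reflect")
                      - ndimage.minimum_filter(image, 3, mode="reflect"))
    maps["sobel_x"] = ndimage.sobel(image, axis=1, mode="reflect")
    maps["sobel_y"] = ndimage.sobel(image, axis=0, mode="reflect")
    maps["sobel_mag"] = np.hypot(maps["sobel_x"], maps["sobel_y"])
    maps["mean5"] = ndimage.uniform_filter(image, 5, mode="reflect")
    maps["median5"] = ndimage.median_filter(image, 5, mode="reflect")
    signal_value = float(image[mask].mean())
    return maps, signal_value


# ---------------------------------------------------------------------------
# CoLlAGe (optional extension set)
# ---------------------------------------------------------------------------

def dominant_orientation(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel principal gradient orientation in [0, pi).

    The orientation is the first principal direction of the gradient
    vectors stacked over the centred window (structure-tensor closed
    form); zero-gradient windows map to 0 by convention.
    """
    gy, gx = np.gradient(np.asarray(image, dtype=float))
    jxx = ndimage.uniform_filter(gx * gx, window, mode="reflect")
    jyy = ndimage.uniform_filter(gy * gy, window, mode="reflect")
    jxy = ndimage.uniform_filter(gx * gy, window, mode="reflect")
    theta = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    return np.mod(theta, np.pi)


def collage_maps(image: np.ndarray, mask: np.ndarray, window: int = 5,
                 n_angle_bins: int = 64) -> dict[str, np.ndarray]:
    """13 gradient-orientation co-occurrence statistic maps."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    theta = dominant_orientation(image, window)
    bins = np.minimum((theta / np.pi * n_angle_bins).astype(np.int64),
                      n_angle_bins - 1)
    maps = _cooc_stat_maps(bins, mask, window, n_angle_bins)
    return {stat: maps[i] for i, stat in enumerate(HARALICK_STATS)}


# ---------------------------------------------------------------------------
# aggregation and the full battery
# ---------------------------------------------------------------------------

def aggregate(feature_map_values: np.ndarray, aggregator: str) -> float:
    """Named statistic of map values pooled over a ROI.

    Skewness and kurtosis are the standardised 3rd / 4th central moments
    (kurtosis is not excess).  Empty input signals a missing value.
    """
    v = np.asarray(feature_map_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty ROI: missing value")
    if aggregator == "mean":
        return float(v.mean())
    m = v.mean()
    m2 = np.mean((v - m) ** 2)
    if aggregator == "sd":
        return float(np.sqrt(m2))
    if m2 <= 1e-300:
        return 0.0
    if aggregator == "skewness":
        return float(np.mean((v - m) ** 3) / m2**1.5)
    if aggregator == "kurtosis":
        return float(np.mean((v - m) ** 4) / m2**2)
    raise ValueError(f"unknown aggregator {aggregator!r}")


def aggregate_over_roi(feature_map: np.ndarray, roi_mask: np.ndarray,
                       aggregator: str = "mean") -> float:
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI: missing value")
    return aggregate(np.asarray(feature_map)[roi_mask], aggregator)


def _slice_maps(image2d: np.ndarray, union2d: np.ndarray,
                config: BatteryConfig) -> dict[tuple, np.ndarray]:
    """Convolution-family response maps for one 2D slice.

    Haralick maps are excluded: their quantization is per-ROI (so that a
    bright or heterogeneous region cannot rescale the gray levels of the
    other ROIs) and handled by the caller.
    """
    maps: dict[tuple, np.ndarray] = {}
    maps[("signal", ())] = image2d
    fo, _ = first_order_maps(image2d, union2d)
    for s in FIRST_ORDER_MAPS:
        maps[("first_order", (("stat", s),))] = fo[s]
    for (lam, th), resp in gabor_maps(image2d, gabor_bank(config)):
        maps[("gabor", (("lam", float(lam)), ("theta", round(float(th), 4))))] = resp
    for name, resp in laws_maps(image2d).items():
        maps[("laws", (("kernel", name),))] = resp
    if config.include_collage:
        cm = collage_maps(image2d, union2d, config.collage_window,
                          config.collage_angle_bins)
        for s in HARALICK_STATS:
            maps[("collage", (("stat", s), ("win", int(config.collage_window))))] = cm[s]
    return maps


def extract_lesion_features(study, ring_set, config: BatteryConfig | None = None,
                            crop_padding_mm: float = 2.0) -> dict[str, float]:
    """Feature values (column name -> value) for one lesion of a study."""
    from radpt.preprocess import crop_to_roi

    config = config or BatteryConfig()
    union = ring_set.union_mask()
    cropped_union, offset = crop_to_roi(union, union, crop_padding_mm,
                                        study.spacing)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, cropped_union.shape))

    roi_masks = {k: m[sl] for k, m in ring_set.roi_masks().items()}
    union_c = cropped_union
    images = {"T2W": study.t2w[sl], "ADC": study.adc[sl]}

    # pool map values across slices per (sequence, map id, roi)
    pooled: dict[tuple, list[np.ndarray]] = {}
    n_slices = union_c.shape[0]
    for seq, vol in images.items():
        for k in range(n_slices):
            if not union_c[k].any():
                continue
            maps = _slice_maps(vol[k], union_c[k], config)
            for map_id, m in maps.items():
                for roi_name, roi in roi_masks.items():
                    if roi[k].any():
                        pooled.setdefault((seq, map_id, roi_name), []).append(
                            m[roi[k]])
        # Haralick: quantize each ROI with its own (volume-pooled) min-max
        for roi_name, roi in roi_masks.items():
            if not roi.any():
                continue
            q = quantize(vol, roi, config.n_levels)
            for w in config.haralick_windows:
                for k in range(n_slices):
                    if not roi[k].any():
                        continue
                    hm = _cooc_stat_maps(q[k], roi[k], w, config.n_levels)
                    for i, s in enumerate(HARALICK_STATS):
                        map_id = ("haralick", (("stat", s), ("win", int(w))))
                        pooled.setdefault((seq, map_id, roi_name), []).append(
                            hm[i][roi[k]])

    out: dict[str, float] = {}
    for spec in battery_specs(config):
        key = (spec.sequence, (spec.family, spec.params), spec.roi)
        vals = pooled.get(key)
        if vals is None:
            out[spec.name] = np.nan
            continue
        try:
            out[spec.name] = aggregate(np.concatenate(vals), spec.aggregator)
        except ValueError:
            out[spec.name] = np.nan
    return out


def extract_all(studies, ring_sets_per_study=None,
                config: BatteryConfig | None = None,
                crop_padding_mm: float = 2.0) -> pd.DataFrame:
    """FeatureTable for a cohort: one row per lesion, canonical columns.

    ``studies`` is a Study or an iterable of them; ring sets are built on
    the fly when not supplied.  Empty rings yield NaN cells (logged) and
    are excluded pair-wise downstream.
    """
    from radpt.rings import build_ring_sets
    from radpt.simdata import Study

    if isinstance(studies, Study):
        studies = [studies]
    studies = list(studies)
    if ring_sets_per_study is None:
        ring_sets_per_study = [build_ring_sets(st) for st in studies]
    config = config or BatteryConfig()

    rows = []
    for st, ring_sets in zip(studies, ring_sets_per_study):
        for les, rs in zip(st.lesions, ring_sets):
            row = {
                "patient_id": st.patient_id,
                "lesion_id": les.lesion_id,
                "risk_label": les.risk_label,
                "pirads": les.pirads,
            }
            feats = extract_lesion_features(st, rs, config, crop_padding_mm)
            n_missing = sum(1 for v in feats.values() if not np.isfinite(v))
            if n_missing:
                logger.info("lesion %s/%s: %d missing feature cells "
                            "(empty rings)", st.patient_id, les.lesion_id,
                            n_missing)
            row.update(feats)
            rows.append(row)
    return pd.DataFrame(rows)


META_COLUMNS = ("patient_id", "lesion_id", "risk_label", "pirads", "cohort")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def feature_metadata(columns) -> dict[str, dict]:
    """JSON-ready sidecar mapping column names to FeatureSpec fields."""
    out = {}
    for c in columns:
        spec = FeatureSpec.from_name(c)
        out[c] = {
            "family": spec.family,
            "params": dict(spec.params),
            "sequence": spec.sequence,
            "roi": spec.roi,
            "aggregator": spec.aggregator,
        }
    return out
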