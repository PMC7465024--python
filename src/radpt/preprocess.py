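"""Geometry and intensity normalisation applied before feature extraction.

Resampling to a uniform in-plane pixel size (default 0.5 mm), slice
interpolation to a target thickness (default 3 mm), a documented
stand-in for scanner-drift standardisation (z-score within the prostate,
or histogram-landmark alignment), and ROI cropping with physical
padding.

Coordinates are 0-based pixel indices; physical position = index x
spacing (pixel-corner origin).  Images are interpolated bilinearly,
masks with nearest neighbour; nearest-neighbour ties at .5 round toward
the lower index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats


@dataclass
class PreprocessConfig:
    target_pixel_spacing: float = 0.5
    target_slice_thickness: float = 3.0
    crop_padding_mm: float = 2.0
    standardization: str = "zscore_in_prostate"

    def __post_init__(self) -> None:
        if self.target_pixel_spacing <= 0 or self.target_slice_thickness <= 0:
            raise ValueError("target spacings must be positive")
        if self.crop_padding_mm < 0:
            raise ValueError("crop padding must be >= 0")
        if self.standardization not in (
            "zscore_in_prostate", "histogram_landmarks", "none",
        ):
            raise ValueError(f"unknown standardization {self.standardization!r}")


def _nearest_low(coords: np.ndarray) -> np.ndarray:
    """Nearest integer with ties at .5 rounded toward the lower index."""
    return np.ceil(coords - 0.5).astype(np.intp)


def resample_to_grid(image: np.ndarray, spacing: float, target_spacing: float,
                     *, is_mask: bool = False):
    """Resample the in-plane axes of a ``(S, H, W)`` volume to a new pixel size.

    Returns ``(resampled, target_spacing)``.  Intensities are bilinearly
    interpolated (nearest-neighbour for masks); the physical extent is
    preserved to within one pixel.
    """
    if spacing <= 0 or target_spacing <= 0:
        raise ValueError("spacing must be positive")
    image = np.asarray(image)
    if spacing == target_spacing:
        return image.copy(), target_spacing
    s, h, w = image.shape
    new_h = max(1, int(round(h * spacing / target_spacing)))
    new_w = max(1, int(round(w * spacing / target_spacing)))
    # output index i sits at physical i*target -> input coord i*target/spacing
    ys = np.arange(new_h) * target_spacing / spacing
    xs = np.arange(new_w) * target_spacing / spacing
    if is_mask:
        yi = np.clip(_nearest_low(ys), 0, h - 1)
        xi = np.clip(_nearest_low(xs), 0, w - 1)
        out = image[:, yi[:, None], xi[None, :]]
        return out.astype(bool) if image.dtype == bool else out, target_spacing
    grid_y, grid_x = np.meshgrid(ys, xs, indexing="ij")
    out = np.empty((s, new_h, new_w), dtype=float)
    for k in range(s):
        out[k] = ndimage.map_coordinates(
            image[k].astype(float), [grid_y, grid_x], order=1, mode="nearest")
    return out, target_spacing


def interpolate_slices(volume: np.ndarray, slice_thickness: float,
                       target_thickness: float, *, is_mask: bool = False):
    """Linearly resample the slice axis to a new thickness.

    Single-slice volumes are returned unchanged with a warning.  Returns
    ``(volume, thickness)``.
    """
    if slice_thickness <= 0 or target_thickness <= 0:
        raise ValueError("thickness must be positive")
    volume = np.asarray(volume)
    if volume.shape[0] < 2:
        warnings.warn("single-slice volume: slice interpolation skipped")
        return volume.copy(), slice_thickness
    if slice_thickness == target_thickness:
        return volume.copy(), target_thickness
    s = volume.shape[0]
    new_s = max(1, int(round(s * slice_thickness / target_thickness)))
    zs = np.arange(new_s) * target_thickness / slice_thickness
    if is_mask:
        zi = np.clip(_nearest_low(zs), 0, s - 1)
        out = volume[zi]
        return out, target_thickness
    zs = np.clip(zs, 0, s - 1)
    z0 = np.floor(zs).astype(int)
    z1 = np.minimum(z0 + 1, s - 1)
    frac = (zs - z0)[:, None, None]
    out = (1 - frac) * volume[z0].astype(float) + frac * volume[z1].astype(float)
    return out, target_thickness


_LANDMARK_QS = np.linspace(0.0, 1.0, 11)
_TEMPLATE = stats.norm.ppf(np.clip(_LANDMARK_QS, 0.005, 0.995))


def standardize_intensity(image: np.ndarray, prostate_mask: np.ndarray,
                          method: str = "zscore_in_prostate") -> np.ndarray:
    """Stand-in for scanner-drift correction.

    ``zscore_in_prostate`` rescales so the within-prostate voxels have
    mean 0 / SD 1; ``histogram_landmarks`` piecewise-linearly maps the
    within-prostate deciles onto a fixed standard-normal template.  Both
    are monotone in the input intensities.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(prostate_mask, dtype=bool)
    if not mask.any():
        raise ValueError("prostate mask is empty")
    vals = image[mask]
    if method == "none":
        return image.copy()
    if method == "zscore_in_prostate":
        sd = vals.std()
        if sd == 0:
            raise ValueError("degenerate input: zero within-mask variance")
        return (image - vals.mean()) / sd
    if method == "histogram_landmarks":
        landmarks = np.quantile(vals, _LANDMARK_QS)
        if landmarks[-1] == landmarks[0]:
            raise ValueError("degenerate input: zero within-mask variance")
        # strictly increasing knots required by interp; collapse duplicates
        keep = np.concatenate(([True], np.diff(landmarks) > 0))
        return np.interp(image, landmarks[keep], _TEMPLATE[keep])
    raise ValueError(f"unknown standardization method {method!r}")


def crop_to_roi(image: np.ndarray, roi_mask: np.ndarray, padding_mm: float,
                spacing):
    """Crop to the ROI bounding box dilated by ``ceil(padding_mm / spacing)``.

    ``spacing`` is per-axis (matching the array axes).  Returns
    ``(cropped, offset)`` where ``offset`` is the lower corner index per
    axis, enabling an exact coordinate round-trip via :func:`paste_back`.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    image = np.asarray(image)
    spacing = np.broadcast_to(np.asarray(spacing, float), (image.ndim,))
    slices = []
    offset = []
    for ax in range(image.ndim):
        proj = roi_mask.any(axis=tuple(i for i in range(image.ndim) if i != ax))
        idx = np.flatnonzero(proj)
        pad = int(np.ceil(padding_mm / spacing[ax]))
        lo = max(0, idx[0] - pad)
        hi = min(image.shape[ax], idx[-1] + 1 + pad)
        slices.append(slice(lo, hi))
        offset.append(lo)
    return image[tuple(slices)].copy(), tuple(offset)


def paste_back(cropped: np.ndarray, offset, full_shape) -> np.ndarray:
    """Inverse of :func:`crop_to_roi` (zeros outside the cropped region)."""
    out = np.zeros(full_shape, dtype=cropped.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, cropped.shape))
    out[sl] = cropped
    return out


def preprocess_study(study, config: PreprocessConfig | None = None):
    """Apply resampling, slice interpolation and standardisation to a study.

    Returns a new Study; masks keep the lesion-inside-prostate invariant
    (lesions are re-intersected with the resampled prostate).
    """
    from radpt.simdata import Lesion, Study

    config = config or PreprocessConfig()
    sz, sy, sx = study.spacing
    if abs(sy - sx) > 1e-9:
        raise ValueError("anisotropic in-plane spacing is not supported")

    def _geom(vol, is_mask):
        v, _ = resample_to_grid(vol, sy, config.target_pixel_spacing,
                                is_mask=is_mask)
        v, _ = interpolate_slices(v, sz, config.target_slice_thickness,
                                  is_mask=is_mask)
        return v

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prostate = _geom(study.prostate_mask, True)
        t2w = _geom(study.t2w, False)
        adc = _geom(study.adc, False)
        lesions = [
            Lesion(l.lesion_id, _geom(l.mask, True) & prostate, l.risk_label,
                   l.pirads)
            for l in study.lesions
        ]
    t2w = standardize_intensity(t2w, prostate, config.standardization)
    adc = standardize_intensity(adc, prostate, config.standardization)
    spacing = (config.target_slice_thickness, config.target_pixel_spacing,
               config.target_pixel_spacing)
    out = Study(study.patient_id, t2w, adc, spacing, prostate, lesions)
    out.validate()
    return out
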