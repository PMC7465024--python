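"""Intra-tumoral ROI and annular peri-tumoral ring masks.

Rings are built per slice from the exact 2D Euclidean distance transform
of the lesion complement (distance in mm via the pixel spacing), as
half-open annuli ``(lower, upper]`` of default width 3 mm out to 12 mm,
clipped to the prostate and excluding every lesion of the patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

ROI_NAMES = ("IT", "PT_0_3", "PT_3_6", "PT_6_9", "PT_9_12")


@dataclass
class RingSet:
    """Intra-tumoral mask plus ordered annular ring masks with mm bounds."""

    it_mask: np.ndarray
    rings: list[tuple[float, float, np.ndarray]]
    spacing: tuple

    def roi_masks(self) -> dict[str, np.ndarray]:
        """Map canonical ROI names (IT, PT_0_3, ...) to their masks."""
        out = {"IT": self.it_mask}
        for lo, hi, mask in self.rings:
            out[f"PT_{int(lo)}_{int(hi)}"] = mask
        return out

    def union_mask(self) -> np.ndarray:
        u = self.it_mask.copy()
        for _, _, m in self.rings:
            u |= m
        return u


def distance_from_lesion(lesion_mask: np.ndarray, spacing) -> np.ndarray:
    """Exact per-slice 2D Euclidean distance (mm) from the lesion.

    Zero inside the lesion.  ``spacing`` is ``(sz, sy, sx)`` for a
    ``(S, H, W)`` mask or ``(sy, sx)`` for a single 2D slice; only the
    in-plane spacings are used (the feature battery is 2D).
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    if lesion_mask.ndim == 2:
        sy, sx = spacing[-2], spacing[-1]
        return ndimage.distance_transform_edt(~lesion_mask, sampling=(sy, sx))
    sy, sx = spacing[-2], spacing[-1]
    out = np.full(lesion_mask.shape, np.inf)
    for k in range(lesion_mask.shape[0]):
        if lesion_mask[k].any():
            out[k] = ndimage.distance_transform_edt(
                ~lesion_mask[k], sampling=(sy, sx))
    return out


def build_rings(lesion_mask: np.ndarray, prostate_mask: np.ndarray,
                other_lesion_masks=(), spacing=(3.0, 0.5, 0.5),
                ring_width_mm: float = 3.0, n_rings: int = 4) -> RingSet:
    """Build the intra-tumoral mask and ``n_rings`` annular peri-tumoral rings.

    Ring ``k`` (1-based) is ``{x : (k-1)*w < d(x) <= k*w}`` intersected
    with the prostate and with every lesion of the patient removed; rings
    near the gland edge may be empty.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    prostate_mask = np.asarray(prostate_mask, dtype=bool)
    if np.any(lesion_mask & ~prostate_mask):
        raise ValueError("lesion mask extends outside the prostate")
    if ring_width_mm <= 0 or n_rings < 1:
        raise ValueError("ring width and count must be positive")
    d = distance_from_lesion(lesion_mask, spacing)
    excluded = lesion_mask.copy()
    for m in other_lesion_masks:
        excluded |= np.asarray(m, dtype=bool)
    rings = []
    for k in range(1, n_rings + 1):
        lo, hi = (k - 1) * ring_width_mm, k * ring_width_mm
        mask = (d > lo) & (d <= hi) & prostate_mask & ~excluded
        rings.append((lo, hi, mask))
    return RingSet(it_mask=lesion_mask.copy(), rings=rings, spacing=tuple(spacing))


def build_ring_sets(study, ring_width_mm: float = 3.0, n_rings: int = 4):
    """RingSet per lesion of a study, excluding the other lesions."""
    out = []
    for les in study.lesions:
        others = [o.mask for o in study.lesions if o is not les]
        out.append(
            build_rings(les.mask, study.prostate_mask, others, study.spacing,
                        ring_width_mm, n_rings)
        )
    return out
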