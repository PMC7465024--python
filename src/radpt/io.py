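"""NIfTI round-trip helpers for studies, masks and ring sets.

Internal array convention is ``(n_slices, H, W)`` with spacing
``(slice_thickness, row_mm, col_mm)``.  On disk the grid is stored
transposed to ``(W, H, n_slices)`` so that NIfTI pixdims line up with
the usual x/y/z ordering.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def save_volume(path, volume: np.ndarray, spacing) -> None:
    sz, sy, sx = spacing
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)),
                          np.diag([sx, sy, sz, 1.0]))
    nib.save(img, str(path))


def load_volume(path):
    """Return ``(volume, spacing)`` with the internal axis convention."""
    img = nib.load(str(path))
    sx, sy, sz = img.header.get_zooms()[:3]
    vol = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    return vol, (float(sz), float(sy), float(sx))


def load_mask(path):
    vol, spacing = load_volume(path)
    return vol > 0.5, spacing


def save_study(study, out_dir) -> None:
    from radpt.simdata import Study  # noqa: F401  (type reference only)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(out_dir / "t2w.nii.gz", study.t2w, study.spacing)
    save_volume(out_dir / "adc.nii.gz", study.adc, study.spacing)
    save_volume(out_dir / "prostate.nii.gz", study.prostate_mask, study.spacing)
    for les in study.lesions:
        save_volume(out_dir / f"{les.lesion_id}.nii.gz", les.mask, study.spacing)


def load_study(study_dir, manifest_rows):
    """Rebuild a :class:`~radpt.simdata.Study` from a saved directory.

    ``manifest_rows`` supplies lesion ids, risk labels and PI-RADS scores
    for this patient (the image files do not carry them).
    """
    from radpt.simdata import Lesion, Study

    study_dir = Path(study_dir)
    t2w, spacing = load_volume(study_dir / "t2w.nii.gz")
    adc, _ = load_volume(study_dir / "adc.nii.gz")
    prostate, _ = load_mask(study_dir / "prostate.nii.gz")
    lesions = []
    for row in manifest_rows:
        mask, _ = load_mask(study_dir / f"{row['lesion_id']}.nii.gz")
        lesions.append(
            Lesion(row["lesion_id"], mask, row["risk_label"], int(row["pirads"]))
        )
    return Study(study_dir.name, t2w.astype(float), adc.astype(float),
                 spacing, prostate, lesions)
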