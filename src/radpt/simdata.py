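"""Synthetic bi-parametric MRI phantom cohorts.

Generates co-registered T2W / ADC multi-slice studies with an elliptical
prostate, blob-shaped lesions, and class-dependent texture (Gaussian
random fields of controllable variance and correlation length) expressed
inside the lesion and — with a separately controllable effect size per
3 mm band — in the 0–12 mm shell surrounding it.  Every downstream stage
of the pipeline is testable against these phantoms without any external
data.

Conventions
-----------
* Volumes are ``(n_slices, H, W)`` float arrays; masks are boolean.
* ``spacing`` is ``(slice_thickness, row_mm, col_mm)``.
* Physical position = index x spacing (pixel-corner origin).
* Risk labels are ``"L"``, ``"I"``, ``"H"`` (D'Amico-style low /
  intermediate / high).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

RISK_CLASSES = ("L", "I", "H")
N_BANDS = 4
BAND_WIDTH_MM = 3.0


class GeometryError(RuntimeError):
    """A lesion cannot be placed inside the prostate under the config."""


@dataclass
class Lesion:
    lesion_id: str
    mask: np.ndarray
    risk_label: str
    pirads: int


@dataclass
class Study:
    """One patient's co-registered T2W + ADC grids with masks and labels."""

    patient_id: str
    t2w: np.ndarray
    adc: np.ndarray
    spacing: tuple[float, float, float]
    prostate_mask: np.ndarray
    lesions: list[Lesion]

    def validate(self) -> None:
        shape = self.t2w.shape
        if self.adc.shape != shape or self.prostate_mask.shape != shape:
            raise ValueError("all grids must share one shape")
        if self.prostate_mask.dtype != bool:
            raise ValueError("prostate mask must be boolean")
        for les in self.lesions:
            if les.mask.shape != shape or les.mask.dtype != bool:
                raise ValueError(f"bad mask for lesion {les.lesion_id}")
            if np.any(les.mask & ~self.prostate_mask):
                raise ValueError(f"lesion {les.lesion_id} not inside prostate")
            if les.risk_label not in RISK_CLASSES:
                raise ValueError(f"unknown risk label {les.risk_label!r}")
            if not 1 <= les.pirads <= 5:
                raise ValueError(f"PI-RADS out of range: {les.pirads}")


def _per_class(value, scale=(0.0, 0.5, 1.0)) -> dict[str, float]:
    """Normalise a scalar or mapping into a per-class effect dict.

    A scalar ``v`` maps to ``{L: 0, I: v/2, H: v}`` so that a single knob
    yields a monotone class gradient.
    """
    if isinstance(value, Mapping):
        return {c: float(value.get(c, 0.0)) for c in RISK_CLASSES}
    v = float(value)
    return {c: v * s for c, s in zip(RISK_CLASSES, scale)}


def _per_class_bands(value) -> dict[str, tuple[float, ...]]:
    """Normalise into ``{class: (band1..band4)}`` peri-tumoral effects."""
    if isinstance(value, Mapping):
        out = {}
        for c in RISK_CLASSES:
            v = value.get(c, 0.0)
            if np.isscalar(v):
                out[c] = (float(v),) * N_BANDS
            else:
                v = tuple(float(x) for x in v)
                if len(v) != N_BANDS:
                    raise ValueError("per-band effect needs 4 entries")
                out[c] = v
        return out
    scalar = _per_class(value)
    return {c: (scalar[c],) * N_BANDS for c in RISK_CLASSES}


@dataclass
class PhantomConfig:
    """Knobs of the phantom generator.

    Effect sizes are dimensionless multiples of ``noise_sd``; they are free
    simulation knobs, not estimates of any real cohort.
    """

    image_size: int = 96
    pixel_spacing: float = 0.5
    slice_thickness: float = 3.0
    n_slices: tuple[int, int] = (3, 5)
    n_patients: int = 40
    two_lesion_prob: float = 0.15
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    it_effect: float | Mapping[str, float] = 0.0
    pt_effect: float | Mapping[str, object] = 0.0
    adc_shift: Mapping[str, float] | None = None
    it_sequences: tuple[str, ...] = ("T2W", "ADC")
    pt_sequences: tuple[str, ...] = ("T2W", "ADC")
    noise_sd: float = 0.08
    patient_offset_sd: float = 0.0  # per-patient global intensity drift, in noise_sd units
    between_patient_sd: float = 0.0  # lognormal per-patient texture-amplitude jitter
    lesion_contrast_sd: float = 0.0  # per-lesion additive contrast noise, in noise_sd units
    correlation_length_mm: float | Mapping[str, float] = 1.0
    lesion_radius_mm: tuple[float, float] = (2.5, 4.0)
    pirads_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.n_patients < 1 or self.image_size < 8:
            raise ValueError("n_patients >= 1 and image_size >= 8 required")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")
        if not 0.0 <= self.pirads_noise <= 1.0:
            raise ValueError("pirads_noise must lie in [0, 1]")
        for eff in (self.it_effects(), ):
            if not all(np.isfinite(v) for v in eff.values()):
                raise ValueError("effect sizes must be finite")
        for bands in self.pt_effects().values():
            if not all(np.isfinite(v) for v in bands):
                raise ValueError("effect sizes must be finite")
        extent = self.image_size * self.pixel_spacing
        need = 2 * (N_BANDS * BAND_WIDTH_MM + self.lesion_radius_mm[1] + 4.0)
        if extent < need:
            raise ValueError(
                f"image extent {extent:.0f} mm too small for prostate plus "
                f"12 mm shell (need >= {need:.0f} mm)"
            )

    # normalised accessors -------------------------------------------------
    def it_effects(self) -> dict[str, float]:
        return _per_class(self.it_effect)

    def pt_effects(self) -> dict[str, tuple[float, ...]]:
        return _per_class_bands(self.pt_effect)

    def adc_shifts(self) -> dict[str, float]:
        if self.adc_shift is not None:
            return {c: float(self.adc_shift.get(c, 0.0)) for c in RISK_CLASSES}
        # default: hypo-intensity scales with the intra-tumoral effect
        return {c: -v for c, v in self.it_effects().items()}

    def corr_lengths(self) -> dict[str, float]:
        if isinstance(self.correlation_length_mm, Mapping):
            return {
                c: float(self.correlation_length_mm.get(c, 1.0))
                for c in RISK_CLASSES
            }
        return {c: float(self.correlation_length_mm) for c in RISK_CLASSES}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# random-field and geometry helpers
# ---------------------------------------------------------------------------

def _grf(shape: tuple[int, int], corr_len_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Gaussian random field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    if corr_len_px <= 0.05:
        return white
    f = ndimage.gaussian_filter(white, corr_len_px, mode="wrap")
    # analytic normalisation: Var = sum of squared kernel weights
    impulse = np.zeros((int(8 * corr_len_px) + 9,) * 2)
    impulse[impulse.shape[0] // 2, impulse.shape[1] // 2] = 1.0
    kern = ndimage.gaussian_filter(impulse, corr_len_px)
    return f / np.sqrt(np.sum(kern**2))


def _grf_aniso(shape: tuple[int, int], sig_y: float, sig_x: float,
               theta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance oriented Gaussian random field (rotated smoothing)."""
    white = rng.standard_normal(shape)
    f = ndimage.rotate(
        ndimage.gaussian_filter(
            ndimage.rotate(white, np.degrees(theta), reshape=False,
                           order=1, mode="wrap"),
            (sig_y, sig_x), mode="wrap"),
        -np.degrees(theta), reshape=False, order=1, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipse_mask(n: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _blob_mask(n: int, cy: float, cx: float, r_px: float, rng: np.random.Generator,
               scale: float = 1.0) -> np.ndarray:
    """Smooth star-convex blob: radius modulated by low-order harmonics."""
    yy, xx = np.mgrid[0:n, 0:n]
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    r_theta = np.full_like(theta, float(r_px))
    for k in (2, 3, 4):
        amp = rng.uniform(0.0, 0.12)
        phase = rng.uniform(0, 2 * np.pi)
        r_theta = r_theta * (1 + amp * np.cos(k * theta + phase))
    return rad <= scale * r_theta


def _draw_risk(rng: np.random.Generator, class_mix: Sequence[float]) -> str:
    return RISK_CLASSES[rng.choice(3, p=np.asarray(class_mix, float))]


def assign_pirads(risk_label: str, pirads_noise: float, rng: np.random.Generator) -> int:
    """Noisy monotone PI-RADS assignment.

    With probability ``1 - pirads_noise`` the label maps L -> {1, 2},
    I -> 3, H -> {4, 5}; otherwise the score is uniform on 1..5.
    """
    if risk_label not in RISK_CLASSES:
        raise ValueError(f"unknown risk label {risk_label!r}")
    if not 0.0 <= pirads_noise <= 1.0:
        raise ValueError("pirads_noise must lie in [0, 1]")
    if rng.random() < pirads_noise:
        return int(rng.integers(1, 6))
    if risk_label == "L":
        return int(rng.integers(1, 3))
    if risk_label == "I":
        return 3
    return int(rng.integers(4, 6))


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _place_lesion(prostate2d: np.ndarray, r_mm: float, spacing: float,
                  rng: np.random.Generator,
                  exclusion: np.ndarray | None = None,
                  clearance_mm: float = 3.0):
    """Sample a lesion centre keeping >= clearance_mm to the gland edge."""
    edt = ndimage.distance_transform_edt(prostate2d, sampling=spacing)
    allowed = edt >= (1.25 * r_mm + clearance_mm)
    if exclusion is not None:
        allowed &= ~exclusion
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        return None
    flat = idx[rng.integers(idx.size)]
    return np.unravel_index(flat, prostate2d.shape)


def generate_study(config: PhantomConfig, patient_index: int) -> Study:
    """Deterministically generate one phantom patient.

    The RNG stream is keyed on ``(config.seed, patient_index)`` so the same
    pair always yields a bit-identical study regardless of call order.
    """
    if patient_index >= config.n_patients:
        raise ValueError("patient_index out of range")
    rng = np.random.default_rng([config.seed, patient_index])
    n = config.image_size
    sp = config.pixel_spacing
    n_slices = int(rng.integers(config.n_slices[0], config.n_slices[1] + 1))
    shape = (n_slices, n, n)

    # prostate: slightly jittered ellipse, mildly tapered across slices
    cy = n / 2 + rng.uniform(-2, 2)
    cx = n / 2 + rng.uniform(-2, 2)
    ay = rng.uniform(0.33, 0.40) * n
    ax = rng.uniform(0.36, 0.43) * n
    mid = (n_slices - 1) / 2
    prostate = np.zeros(shape, dtype=bool)
    for k in range(n_slices):
        taper = 1.0 - 0.06 * abs(k - mid)
        prostate[k] = _ellipse_mask(n, cy, cx, taper * ay, taper * ax)

    # lesions -------------------------------------------------------------
    n_lesions = 2 if rng.random() < config.two_lesion_prob else 1
    core = prostate[int(round(mid))]
    lesions: list[Lesion] = []
    exclusion: np.ndarray | None = None
    for j in range(n_lesions):
        r_mm = rng.uniform(*config.lesion_radius_mm)
        centre = _place_lesion(core, r_mm, sp, rng, exclusion=exclusion)
        if centre is None:
            if j == 0:
                raise GeometryError(
                    f"no feasible lesion centre for patient {patient_index}"
                )
            break  # multi-focal placement infeasible; keep single lesion
        ly, lx = centre
        blob_key = [config.seed, patient_index, j, 7]
        blob2d = _blob_mask(n, ly, lx, r_mm / sp, np.random.default_rng(blob_key))
        blob2d_taper = _blob_mask(n, ly, lx, r_mm / sp,
                                  np.random.default_rng(blob_key), scale=0.7)
        span = int(rng.integers(1, n_slices + 1))
        s0 = int(rng.integers(0, n_slices - span + 1))
        mask = np.zeros(shape, dtype=bool)
        for k in range(s0, s0 + span):
            end = span >= 3 and k in (s0, s0 + span - 1)
            mask[k] = blob2d_taper if end else blob2d
        mask &= prostate
        if blob2d.sum() == 0 or mask.sum() == 0:
            raise GeometryError("degenerate lesion mask")
        risk = _draw_risk(rng, config.class_mix)
        pirads = assign_pirads(risk, config.pirads_noise, rng)
        lesions.append(Lesion(f"les{j}", mask, risk, pirads))
        dil = ndimage.binary_dilation(
            blob2d, iterations=int(np.ceil((r_mm + 4.0) / sp)))
        exclusion = dil if exclusion is None else (exclusion | dil)

    # intensity synthesis -------------------------------------------------
    it_eff = config.it_effects()
    pt_eff = config.pt_effects()
    adc_shift = config.adc_shifts()
    corr = config.corr_lengths()
    nsd = config.noise_sd
    base_len_px = 1.0 / sp  # 1 mm background correlation length
    # per-patient texture-amplitude jitter (between-patient variability);
    # rng stream is untouched when the knob is off
    amp_seq = {"T2W": nsd, "ADC": nsd}
    len_jitter = 1.0
    if config.between_patient_sd > 0:
        for s_name in ("T2W", "ADC"):
            amp_seq[s_name] = nsd * np.exp(
                config.between_patient_sd * rng.standard_normal())
        # correlation structure varies between patients too, otherwise
        # quantization-invariant texture statistics separate classes
        # deterministically at any effect size
        len_jitter = np.exp(
            0.5 * config.between_patient_sd * rng.standard_normal())
    base_len_px *= len_jitter

    t2w = np.empty(shape)
    adc = np.empty(shape)
    for k in range(n_slices):
        soft = ndimage.gaussian_filter(prostate[k].astype(float), 2.0)
        t2w[k] = 0.55 + 0.45 * soft + amp_seq["T2W"] * _grf((n, n), base_len_px, rng)
        adc[k] = 0.80 + 0.50 * soft + amp_seq["ADC"] * _grf((n, n), base_len_px, rng)
    if config.patient_offset_sd > 0:
        t2w += config.patient_offset_sd * nsd * rng.standard_normal()
        adc += config.patient_offset_sd * nsd * rng.standard_normal()

    for les in lesions:
        eff = it_eff[les.risk_label]
        ell = corr[les.risk_label] / sp * len_jitter
        other = np.zeros(shape, dtype=bool)
        for o in lesions:
            if o is not les:
                other |= o.mask
        # lesion conspicuity varies between patients: without this, edge
        # (zero-sum) kernels read the lesion-boundary step noise-free
        cjit_t2w = cjit_adc = 0.0
        if config.lesion_contrast_sd > 0:
            cjit_t2w = config.lesion_contrast_sd * rng.standard_normal()
            cjit_adc = config.lesion_contrast_sd * rng.standard_normal()
        for k in range(n_slices):
            m = les.mask[k]
            if m.any():
                if "T2W" in config.it_sequences and eff > 0:
                    t2w[k][m] += np.sqrt(eff) * amp_seq["T2W"] * _grf(
                        (n, n), ell, rng)[m]
                    t2w[k][m] -= 0.5 * eff * nsd
                t2w[k][m] += cjit_t2w * nsd
                adc[k][m] += (adc_shift[les.risk_label] + cjit_adc) * nsd
                if "ADC" in config.it_sequences and eff > 0:
                    adc[k][m] += np.sqrt(eff) * amp_seq["ADC"] * _grf(
                        (n, n), ell, rng)[m]
            # peri-tumoral bands: 2D distance from this lesion, per slice
            if not les.mask[k].any():
                continue
            d = ndimage.distance_transform_edt(~les.mask[k], sampling=sp)
            for b in range(N_BANDS):
                eff_b = pt_eff[les.risk_label][b]
                if eff_b <= 0:
                    continue
                band = (
                    (d > b * BAND_WIDTH_MM)
                    & (d <= (b + 1) * BAND_WIDTH_MM)
                    & prostate[k]
                    & ~other[k]
                )
                if not band.any():
                    continue
                # band effect: mild hyper-intensity plus three independent
                # texture components (coarse isotropic, fine isotropic,
                # oriented) so that "which ring carries signal" is a
                # multi-dimensional, recoverable ground truth
                for seq_name, img in (("T2W", t2w), ("ADC", adc)):
                    if seq_name not in config.pt_sequences:
                        continue
                    amp = np.sqrt(eff_b / 3.0) * amp_seq[seq_name]
                    tex = (
                        _grf((n, n), ell, rng)
                        + _grf((n, n), 0.5 / sp, rng)
                        + _grf_aniso((n, n), 3.0 / sp, 0.7 / sp, 0.5, rng)
                    )
                    img[k][band] += amp * tex[band]
                    img[k][band] += 0.4 * eff_b * nsd

    study = Study(
        patient_id=f"P{patient_index:04d}",
        t2w=t2w,
        adc=adc,
        spacing=(config.slice_thickness, sp, sp),
        prostate_mask=prostate,
        lesions=lesions,
    )
    study.validate()
    return study


def generate_cohort(config: PhantomConfig, out_dir=None):
    """Generate all patients of a cohort plus the manifest table.

    Returns ``(studies, manifest)`` where the manifest has one row per
    lesion (patient_id, lesion_id, risk_label, pirads, n_slices).  When
    ``out_dir`` is given, NIfTI images/masks and ``manifest.csv`` are
    written there.
    """
    import pandas as pd

    studies = [generate_study(config, i) for i in range(config.n_patients)]
    rows = []
    for st in studies:
        for les in st.lesions:
            rows.append(
                {
                    "patient_id": st.patient_id,
                    "lesion_id": les.lesion_id,
                    "risk_label": les.risk_label,
                    "pirads": les.pirads,
                    "n_slices": st.t2w.shape[0],
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from radpt.io import save_study

        out_dir.mkdir(parents=True, exist_ok=True)
        for st in studies:
            save_study(st, out_dir / st.patient_id)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return studies, manifest
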