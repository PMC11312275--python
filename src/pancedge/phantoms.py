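"""Synthetic two-phase phantom images with exactly known border roughness.

A phantom emulates the parenchyma/fat interface sampled by a CT ROI: a
two-level step image whose border is a smooth base curve (a straight line at
a configurable angle, or a circular arc) plus a band-limited roughness
perturbation of known root-mean-square amplitude. The true border polyline
and its realized RMS are recorded *before* blur and noise are applied, so
every downstream stage (edge detection, baseline fitting, scoring,
statistics) can be validated against exact ground truth.

The perturbation is a sum of sinusoids with wavelengths drawn uniformly from
a configurable band and uniform random phases, rescaled so that the realized
RMS about the base curve matches the requested amplitude. A band-limited
model (rather than white noise) keeps the roughness wavelengths above the
edge detector's resolution and below the baseline spline's flexibility,
which makes score-versus-truth comparisons well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import PhantomError
from .imgio import GrayImage, ROIBox, save_image

__all__ = [
    "BaseCurve",
    "PhantomSpec",
    "PhantomTruth",
    "PatientPhantoms",
    "make_phantom",
    "make_cohort",
    "write_cohort",
    "centered_roi",
]

#: Dense sampling step (px of arc length) for the ground-truth border polyline.
_TRUTH_STEP = 0.25


@dataclass(frozen=True)
class BaseCurve:
    """Smooth underlying border geometry, before roughness is added.

    ``kind="line"`` is a straight border through the image center at
    ``angle_deg`` degrees from the column axis; ``kind="arc"`` is a circular
    arc of radius ``radius`` px tangent to that line at the image center.
    An optional long-wavelength "bend" (organ-scale curvature) can be added;
    it belongs to the base geometry and is *not* counted as roughness.
    """

    kind: str = "line"
    angle_deg: float = 0.0
    radius: float | None = None
    bend_amplitude: float = 0.0
    bend_wavelength: float | None = None
    bend_phase: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("line", "arc"):
            raise PhantomError(f"unknown base curve kind {self.kind!r}")
        if self.kind == "arc" and (self.radius is None or self.radius <= 0):
            raise PhantomError("arc base curve requires a positive radius")
        if self.bend_amplitude != 0.0 and (
            self.bend_wavelength is None or self.bend_wavelength <= 0
        ):
            raise PhantomError("bend requires a positive bend_wavelength")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of a synthetic two-phase image.

    Defaults are the package's reference study conditions: a 64x64 image
    with parenchyma-like level 110 inside and fat-like level 20 outside,
    roughness wavelengths 4-12 px, a 1 px Gaussian point spread and 2 gray
    levels of additive noise. ``seed`` fully determines the output.
    """

    shape: tuple[int, int] = (64, 64)
    base_curve: BaseCurve = BaseCurve()
    perturbation_rms: float = 0.0
    band: tuple[float, float] = (4.0, 12.0)
    contrast: tuple[float, float] = (110.0, 20.0)
    blur_sigma: float = 1.0
    noise_sigma: float = 2.0
    seed: int = 0
    n_components: int = 12
    supersample: int = 4

    def validate(self) -> None:
        rows, cols = self.shape
        if rows < 16 or cols < 16:
            raise PhantomError(f"image must be at least 16x16, got {self.shape}")
        if self.perturbation_rms < 0:
            raise PhantomError("perturbation_rms must be >= 0")
        lo, hi = self.band
        if lo < 2.0:
            raise PhantomError("min wavelength must be >= 2 px (Nyquist)")
        if hi < lo:
            raise PhantomError(f"band must satisfy min <= max, got {self.band}")
        if self.contrast[0] == self.contrast[1]:
            raise PhantomError("inside and outside gray levels must differ")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise PhantomError("blur_sigma and noise_sigma must be >= 0")
        if self.n_components < 1:
            raise PhantomError("n_components must be >= 1")
        if self.supersample < 1:
            raise PhantomError("supersample must be >= 1")
        self.base_curve.validate()


@dataclass(frozen=True)
class PhantomTruth:
    """Exact border geometry of a phantom.

    ``border_points`` is a dense ``(N, 2)`` polyline of ``(row, col)``
    sub-pixel border coordinates inside the image; ``true_rms`` is the
    realized RMS of the roughness perturbation about the base curve, px.
    """

    border_points: np.ndarray
    true_rms: float


def _frame(curve: BaseCurve):
    """Tangent/normal unit vectors of the base line, in (x=col, y=row)."""
    theta = np.deg2rad(curve.angle_deg)
    t = np.array([np.cos(theta), np.sin(theta)])  # (x, y)
    n = np.array([-t[1], t[0]])
    return t, n


def _curve_uv(spec: PhantomSpec, x, y):
    """Map image coordinates to (u, v): arc length along / offset across the base curve."""
    rows, cols = spec.shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    t, n = _frame(spec.base_curve)
    dx, dy = x - cx, y - cy
    if spec.base_curve.kind == "line":
        u = dx * t[0] + dy * t[1]
        v = dx * n[0] + dy * n[1]
        return u, v
    R = float(spec.base_curve.radius)
    # Arc center sits a radius away from the image center along -n.
    ax, ay = cx - R * n[0], cy - R * n[1]
    qx, qy = x - ax, y - ay
    r = np.hypot(qx, qy)
    # Signed angle from the reference radial direction (+n), positive toward +t.
    phi = np.arctan2(qx * t[0] + qy * t[1], qx * n[0] + qy * n[1])
    return R * phi, r - R


def _curve_points(spec: PhantomSpec, u, offset):
    """Image (row, col) coordinates of points at (u, v=offset) on the base frame."""
    rows, cols = spec.shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    t, n = _frame(spec.base_curve)
    if spec.base_curve.kind == "line":
        x = cx + u * t[0] + offset * n[0]
        y = cy + u * t[1] + offset * n[1]
        return np.column_stack([y, x])
    R = float(spec.base_curve.radius)
    ax, ay = cx - R * n[0], cy - R * n[1]
    phi = u / R
    radial_x = n[0] * np.cos(phi) + t[0] * np.sin(phi)
    radial_y = n[1] * np.cos(phi) + t[1] * np.sin(phi)
    x = ax + (R + offset) * radial_x
    y = ay + (R + offset) * radial_y
    return np.column_stack([y, x])


def _bend(curve: BaseCurve, u):
    if curve.bend_amplitude == 0.0:
        return np.zeros_like(u)
    return curve.bend_amplitude * np.sin(
        2 * np.pi * u / curve.bend_wavelength + curve.bend_phase
    )


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, PhantomTruth]:
    """Render a phantom and return it with its exact border ground truth.

    The truth is computed before blur and noise are applied; equal specs
    yield bit-identical images.
    """
    spec.validate()
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)
    lam = rng.uniform(spec.band[0], spec.band[1], spec.n_components)
    phase = rng.uniform(0.0, 2 * np.pi, spec.n_components)

    # Dense parameterization generously covering the image.
    max_off = abs(spec.base_curve.bend_amplitude) + 4 * spec.perturbation_rms
    half_span = 0.5 * float(np.hypot(rows, cols)) + max_off + 2.0
    if spec.base_curve.kind == "arc":
        half_span = min(half_span, 0.95 * np.pi * float(spec.base_curve.radius))
    u_grid = np.arange(-half_span, half_span + _TRUTH_STEP, _TRUTH_STEP)

    def raw_perturbation(u):
        acc = np.zeros_like(u, dtype=float)
        for k in range(spec.n_components):
            acc += np.sin(2 * np.pi * u / lam[k] + phase[k])
        return acc

    base_pts = _curve_points(spec, u_grid, _bend(spec.base_curve, u_grid))
    in_img = (
        (base_pts[:, 0] >= 0)
        & (base_pts[:, 0] <= rows - 1)
        & (base_pts[:, 1] >= 0)
        & (base_pts[:, 1] <= cols - 1)
    )
    if not in_img.any():
        raise PhantomError("base curve does not intersect the image")
    extent = u_grid[in_img].max() - u_grid[in_img].min()

    if spec.perturbation_rms > 0:
        min_len = 2.0 * spec.band[1]
        if extent < min_len:
            raise PhantomError(
                f"border length {extent:.1f} px too short for wavelengths up to "
                f"{spec.band[1]:.1f} px; minimum border length is {min_len:.1f} px"
            )
        raw = raw_perturbation(u_grid)
        rms0 = float(np.sqrt(np.mean(raw[in_img] ** 2)))
        scale = spec.perturbation_rms / rms0 if rms0 > 0 else 0.0
    else:
        scale = 0.0

    def perturbation(u):
        if scale == 0.0:
            return np.zeros_like(u, dtype=float)
        return scale * raw_perturbation(u)

    psi = perturbation(u_grid)
    true_pts = _curve_points(spec, u_grid, _bend(spec.base_curve, u_grid) + psi)
    in2 = (
        (true_pts[:, 0] >= 0)
        & (true_pts[:, 0] <= rows - 1)
        & (true_pts[:, 1] >= 0)
        & (true_pts[:, 1] <= cols - 1)
        & in_img
    )
    true_rms = float(np.sqrt(np.mean(psi[in2] ** 2))) if spec.perturbation_rms > 0 else 0.0
    truth = PhantomTruth(border_points=true_pts[in2], true_rms=true_rms)

    # Anti-aliased rasterization: per-pixel coverage from an m x m subsample
    # grid, so the sub-pixel border position is meaningful.
    m = spec.supersample
    offs = (np.arange(m) + 0.5) / m - 0.5
    rr = (np.arange(rows)[:, None] + offs[None, :]).ravel()
    cc = (np.arange(cols)[:, None] + offs[None, :]).ravel()
    Y, X = np.meshgrid(rr, cc, indexing="ij")
    u, v = _curve_uv(spec, X, Y)
    inside = v <= _bend(spec.base_curve, u) + perturbation(u)
    coverage = inside.reshape(rows, m, cols, m).mean(axis=(1, 3))

    inside_level, outside_level = spec.contrast
    img = outside_level + (inside_level - outside_level) * coverage
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return GrayImage(pixels=img), truth


@dataclass
class PatientPhantoms:
    """One simulated patient: a tumor-like (smooth) and a healthy-like (rough) phantom."""

    patient_id: str
    tumor_spec: PhantomSpec
    tumor_image: GrayImage
    tumor_truth: PhantomTruth
    healthy_spec: PhantomSpec
    healthy_image: GrayImage
    healthy_truth: PhantomTruth


def make_cohort(
    n_patients: int,
    tumor_template: PhantomSpec,
    healthy_template: PhantomSpec,
    seed: int,
) -> list[PatientPhantoms]:
    """Generate a paired phantom cohort from two spec templates.

    Patient ``i`` uses seed ``seed + i`` in both arms, so any single pair can
    be regenerated without rebuilding the cohort. The tumor arm conventionally
    carries the smoother (lower ``perturbation_rms``) template, mirroring the
    smooth desmoplastic tumor margin versus the lobulated healthy parenchyma.
    """
    if n_patients < 2:
        raise PhantomError(f"cohort needs at least 2 patients, got {n_patients}")
    cohort = []
    for i in range(n_patients):
        spec_t = replace(tumor_template, seed=seed + i)
        spec_h = replace(healthy_template, seed=seed + i)
        img_t, tr_t = make_phantom(spec_t)
        img_h, tr_h = make_phantom(spec_h)
        cohort.append(
            PatientPhantoms(
                patient_id=f"P{i + 1:03d}",
                tumor_spec=spec_t,
                tumor_image=img_t,
                tumor_truth=tr_t,
                healthy_spec=spec_h,
                healthy_image=img_h,
                healthy_truth=tr_h,
            )
        )
    return cohort


def centered_roi(shape: tuple[int, int], roi_shape: tuple[int, int], label: str = "") -> ROIBox:
    """ROI of ``roi_shape`` centered in an image of ``shape`` (border runs through it)."""
    rows, cols = shape
    h, w = roi_shape
    return ROIBox(top=(rows - h) // 2, left=(cols - w) // 2, height=h, width=w, label=label)


def write_cohort(
    cohort: list[PatientPhantoms],
    out_dir,
    roi_shape: tuple[int, int] = (40, 40),
    fmt: str = "png",
) -> Path:
    """Write a cohort to disk and return the manifest path.

    Each patient's two phantoms are composited side by side (tumor left,
    healthy right) into one image, with the two constant-size boxes centered
    on the respective borders — the on-disk analog of annotating two ROIs per
    patient. The manifest CSV carries the ROIs, ground-truth roughness and
    per-patient seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows_out = []
    for pat in cohort:
        rows, cols = pat.tumor_image.shape
        if pat.healthy_image.shape != (rows, cols):
            raise PhantomError("cohort arms must share one image shape")
        canvas = np.concatenate([pat.tumor_image.pixels, pat.healthy_image.pixels], axis=1)
        img_path = out_dir / f"{pat.patient_id}.{fmt}"
        save_image(GrayImage(pixels=canvas), img_path)
        roi_t = centered_roi((rows, cols), roi_shape, label="tumor")
        roi_h = centered_roi((rows, cols), roi_shape, label="healthy")
        roi_h = ROIBox(
            top=roi_h.top, left=roi_h.left + cols,
            height=roi_h.height, width=roi_h.width, label="healthy",
        )
        rows_out.append(
            {
                "patient_id": pat.patient_id,
                "image_path": img_path.name,
                "roi_tumor": roi_t.to_string(),
                "roi_healthy": roi_h.to_string(),
                "true_rms_tumor": pat.tumor_truth.true_rms,
                "true_rms_healthy": pat.healthy_truth.true_rms,
                "seed": pat.tumor_spec.seed,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows_out).to_csv(manifest_path, index=False)
    return manifest_path
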