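"""The pancreatic margin score (PMS): spline baseline fit and RMS residual.

The "average boundary line" is a least-squares cubic spline of the border's
perpendicular offset v against its axial coordinate u, with uniformly spaced
interior knots. The spline is deliberately stiff — default knot spacing is a
quarter of the ROI width — so that organ-scale curvature is absorbed into
the baseline while nodularity at wavelengths well below the knot spacing
stays in the residuals. The PMS is the root-mean-square of those residuals,
in pixels: a smooth margin (as produced by the desmoplastic reaction of a
ductal adenocarcinoma) yields a *low* score, a lobulated healthy parenchyma
a *high* one.

Residuals are measured perpendicular to the principal axis (``v - v_hat(u)``),
not along the local normal of the fitted curve; the two differ by
O(slope^2), negligible for borders roughly aligned with their axis. Knot
spacing is the critical stiffness parameter and is recorded, together with
every other score-influencing setting, in a parameter fingerprint carried by
each result.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline

from .edgecore import (
    BorderCurve,
    CannyParams,
    canny_edges,
    extract_border,
    parameterize_border,
    refine_subpixel,
)
from .errors import EdgeError, FitError, PancedgeError, StageError
from .imgio import GrayImage, ROIBox, crop

__all__ = [
    "DEFAULT_THRESHOLD_PX",
    "SmoothBoundary",
    "PMSResult",
    "fit_average_boundary",
    "compute_pms",
    "score_roi",
    "classify",
    "params_fingerprint",
]

#: Published single-center, single-scanner threshold separating cancerous
#: (below) from healthy (above) margin scores, in pixels. A calibration
#: constant for *that* study's scanner and protocol — not a universal value.
DEFAULT_THRESHOLD_PX = 0.6855


@dataclass
class SmoothBoundary:
    """The fitted average boundary line and the residuals about it."""

    spline: BSpline
    interior_knots: np.ndarray
    residuals: np.ndarray
    u: np.ndarray
    v: np.ndarray
    knots_used: int

    def __call__(self, u):
        return self.spline(u)


@dataclass(frozen=True)
class PMSResult:
    """Root-mean-square deviation of a border from its average boundary line."""

    pms: float
    n_points: int
    roi_label: str
    knots_used: int
    params_fingerprint: str
    pms_mm: float | None = None

    def to_dict(self) -> dict:
        out = {
            "pms": self.pms,
            "n_points": self.n_points,
            "roi_label": self.roi_label,
            "knots_used": self.knots_used,
            "params_fingerprint": self.params_fingerprint,
        }
        if self.pms_mm is not None:
            out["pms_mm"] = self.pms_mm
        return out


def params_fingerprint(canny: CannyParams, knot_spacing: float, subpixel: bool) -> str:
    """Short stable hash of every parameter that influences a score."""
    payload = json.dumps(
        {
            "sigma": canny.sigma,
            "high_quantile": canny.high_quantile,
            "low_fraction": canny.low_fraction,
            "knot_spacing": knot_spacing,
            "subpixel": subpixel,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def fit_average_boundary(curve: BorderCurve, knot_spacing: float) -> SmoothBoundary:
    """Fit the average boundary line: a least-squares cubic spline of v on u.

    Interior knots are spaced uniformly at ``knot_spacing`` px along the
    border's u-range. When the border carries fewer points than the spline
    has coefficients (or the knots violate the Schoenberg-Whitney
    interlacing), the knot count is reduced until the fit is solvable; the
    count actually used is recorded in ``knots_used``.
    """
    if curve.u is None or curve.v is None:
        raise FitError("border curve is not parameterized")
    if knot_spacing <= 0:
        raise FitError("knot_spacing must be > 0")
    u, v = curve.u, curve.v
    span = float(u[-1] - u[0])
    if span < 2 * knot_spacing:
        raise FitError(
            f"border too short for baseline fit (u-range {span:.1f} px "
            f"< 2 x knot spacing {knot_spacing:.1f} px)"
        )
    n_interior = int(np.round(span / knot_spacing)) - 1
    n_interior = min(n_interior, len(u) - 4)  # never more coefficients than points
    if n_interior < 1:
        raise FitError("border too short for baseline fit (no room for interior knots)")

    last_err: Exception | None = None
    while n_interior >= 1:
        interior = u[0] + np.arange(1, n_interior + 1) * span / (n_interior + 1)
        knots = np.concatenate([[u[0]] * 4, interior, [u[-1]] * 4])
        try:
            spline = make_lsq_spline(u, v, knots, k=3)
        except (ValueError, np.linalg.LinAlgError) as exc:
            last_err = exc
            n_interior -= 1
            continue
        residuals = v - spline(u)
        return SmoothBoundary(
            spline=spline,
            interior_knots=interior,
            residuals=residuals,
            u=u,
            v=v,
            knots_used=n_interior,
        )
    raise FitError(f"baseline fit failed even with one interior knot: {last_err}")


def compute_pms(
    boundary: SmoothBoundary,
    roi_label: str = "",
    fingerprint: str = "",
    spacing: tuple[float, float] | None = None,
) -> PMSResult:
    """Root-mean-square of the baseline residuals, in pixels.

    A millimeter value is reported alongside only when (near-isotropic)
    pixel spacing is known; the score itself stays in pixel units.
    """
    res = np.asarray(boundary.residuals, dtype=float)
    if res.size == 0:
        raise FitError("no residuals to score")
    pms = float(np.sqrt(np.mean(res**2)))
    pms_mm = None
    if spacing is not None and abs(spacing[0] - spacing[1]) < 1e-6 * max(spacing):
        pms_mm = pms * spacing[0]
    return PMSResult(
        pms=pms,
        n_points=int(res.size),
        roi_label=roi_label,
        knots_used=boundary.knots_used,
        params_fingerprint=fingerprint,
        pms_mm=pms_mm,
    )


def score_roi(
    image: GrayImage,
    roi: ROIBox,
    canny: CannyParams | None = None,
    knot_spacing: float | None = None,
    subpixel: bool = False,
) -> PMSResult:
    """Full scoring chain: crop, detect, select, parameterize, fit, score.

    ``knot_spacing`` defaults to a quarter of the ROI width. Any failure in
    an intermediate stage is re-raised as a :class:`StageError` whose message
    names the stage, e.g. ``"canny_edges/no edges"``.
    """
    if canny is None:
        canny = CannyParams()
    if knot_spacing is None:
        knot_spacing = roi.width / 4.0
    fingerprint = params_fingerprint(canny, knot_spacing, subpixel)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except PancedgeError as exc:
            raise StageError(name, str(exc)) from exc

    roi_img = _stage("crop", crop, image, roi)
    edges = _stage("canny_edges", canny_edges, roi_img, canny)
    if edges.is_empty:
        raise StageError("canny_edges", edges.flag or "no edges")
    curve = _stage("extract_border", extract_border, edges)
    if subpixel:
        curve = _stage("refine_subpixel", refine_subpixel, curve, edges)
    curve = _stage("parameterize_border", parameterize_border, curve)
    boundary = _stage("fit_average_boundary", fit_average_boundary, curve, knot_spacing)
    return _stage(
        "compute_pms",
        compute_pms,
        boundary,
        roi.label,
        fingerprint,
        image.spacing,
    )


def classify(pms: float, threshold: float = DEFAULT_THRESHOLD_PX) -> str:
    """Threshold rule: scores *below* the threshold are called cancer.

    The desmoplastic tumor margin is smooth (low score) while healthy
    parenchyma is lobulated (high score); a score exactly at the threshold
    is called healthy.
    """
    if pms < 0:
        raise PancedgeError("pms must be >= 0")
    if threshold <= 0:
        raise PancedgeError("threshold must be > 0")
    return "cancer" if pms < threshold else "healthy"
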