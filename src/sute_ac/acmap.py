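"""511 keV attenuation-coefficient (AC) map construction and conversions.

From segmentation posteriors the method assigns air 0, soft tissue
0.100 cm^-1 and bone either a fixed 0.151 cm^-1 (sUTE-fix) or a continuous
value from a monotone cubic R2* -> mu calibration (sUTE-cont), then smooths
with a 2-mm FWHM Gaussian. A six-class variant (mcAC) additionally
distinguishes GM/WM/CSF (0.099/0.099/0.096 cm^-1). The reference map comes
from ground-truth labels with no smoothing. CT volumes are converted with a
standard bilinear HU model anchored at air and water, and classification
rules for CT (-500/300 HU) and vendor UTE maps (exactly 0.151 / 0 cm^-1)
support the evaluation-side comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import SegmentationResult, hard_label
from .volume import LabelMask, Volume, gaussian_smooth


@dataclass(frozen=True)
class ACCoefficients:
    """Tissue-wise linear attenuation coefficients at 511 keV, cm^-1."""

    air: float = 0.0
    soft: float = 0.100
    bone: float = 0.151
    gm: float = 0.099
    wm: float = 0.099
    csf: float = 0.096

    def __post_init__(self) -> None:
        if self.air != 0.0:
            raise ValueError("air attenuation must be exactly 0")
        for name in ("soft", "bone", "gm", "wm", "csf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} attenuation must be >= 0")

    def for_class(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class CalibrationFit:
    """Cubic polynomial mapping R2* (1/ms) to bone mu (cm^-1).

    ``coeffs`` are c0..c3 (ascending powers). The mapping is clamped to
    ``mu_clamp`` and verified non-decreasing over ``r2s_range`` at fit time.
    """

    coeffs: tuple[float, float, float, float]
    r2s_range: tuple[float, float]
    mu_clamp: tuple[float, float] = (0.100, 0.20)

    def __post_init__(self) -> None:
        if len(self.coeffs) != 4:
            raise ValueError("calibration must be a degree-3 polynomial (4 coefficients)")
        if not _is_monotone(self.coeffs, self.r2s_range):
            raise ValueError("calibration polynomial is not non-decreasing over its range")

    def __call__(self, r2s: np.ndarray) -> np.ndarray:
        r = np.clip(np.asarray(r2s, dtype=np.float64), *self.r2s_range)
        mu = np.polynomial.polynomial.polyval(r, np.asarray(self.coeffs))
        return np.clip(mu, *self.mu_clamp)


def _is_monotone(coeffs, r2s_range, n: int = 512) -> bool:
    c = np.asarray(coeffs, dtype=np.float64)
    deriv = np.polynomial.polynomial.polyder(c)
    grid = np.linspace(r2s_range[0], r2s_range[1], n)
    return bool(np.all(np.polynomial.polynomial.polyval(grid, deriv) >= -1e-9))


def fit_r2star_calibration(r2s_samples, mu_samples, degree: int = 3,
                           mu_clamp: tuple[float, float] = (0.100, 0.20)
                           ) -> CalibrationFit:
    """Least-squares cubic fit of (R2*, mu) sample pairs.

    Requires at least 8 pairs spanning the bone R2* range; a fit that is not
    non-decreasing over the sample range is rejected.
    """
    r = np.asarray(r2s_samples, dtype=np.float64).ravel()
    m = np.asarray(mu_samples, dtype=np.float64).ravel()
    if r.size != m.size:
        raise ValueError("sample length mismatch")
    if r.size < 8:
        raise ValueError("need at least 8 (R2*, mu) sample pairs")
    if degree != 3:
        raise ValueError("calibration degree is fixed at 3")
    if np.ptp(r) <= 0:
        raise ValueError("rank-deficient design: R2* samples do not span a range")
    series = np.polynomial.Polynomial.fit(r, m, deg=degree)
    coeffs = tuple(float(c) for c in series.convert().coef)
    coeffs = coeffs + (0.0,) * (4 - len(coeffs))
    rng = (float(np.min(r)), float(np.max(r)))
    if not _is_monotone(coeffs, rng):
        raise ValueError("fitted calibration is not monotone over the sample range")
    return CalibrationFit(coeffs, rng, mu_clamp)


def default_r2star_calibration(coeffs: ACCoefficients | None = None) -> CalibrationFit:
    """Calibration anchored at (0 /ms -> soft mu) and (2.0 /ms -> bone mu).

    The cubic of the original R2*-to-mu transformation is not public; this
    default interpolates the two physical anchors linearly over 0..3 /ms and
    fits the cubic to those samples. Results in continuous mode are therefore
    calibration-dependent.
    """
    coeffs = coeffs or ACCoefficients()
    r = np.linspace(0.0, 3.0, 13)
    mu = coeffs.soft + (coeffs.bone - coeffs.soft) * r / 2.0
    return fit_r2star_calibration(r, mu, mu_clamp=(coeffs.soft, 0.20))


def make_ac_map(seg: SegmentationResult, coeffs: ACCoefficients | None = None,
                mode: str = "fix", r2s: Volume | None = None,
                calib: CalibrationFit | None = None,
                smoothing_fwhm_mm: float = 2.0,
                air_threshold: float = 0.1, bone_threshold: float = 0.2,
                coverage_mask: Volume | None = None,
                fallback: Volume | None = None) -> Volume:
    """sUTE attenuation map from segmentation posteriors.

    ``mode="fix"`` assigns the constant bone coefficient; ``mode="cont"``
    maps R2* through the calibration polynomial at bone voxels. The
    assembled map is Gaussian-smoothed (FWHM in mm), then fallback values
    are pasted unsmoothed where ``coverage_mask`` is zero.
    """
    coeffs = coeffs or ACCoefficients()
    if mode not in ("fix", "cont"):
        raise ValueError("mode must be 'fix' or 'cont'")
    if mode == "cont" and (r2s is None or calib is None):
        raise ValueError("continuous mode requires an R2* map and a calibration")
    labels = hard_label(seg, air_threshold, bone_threshold)
    ref = seg.posteriors["air"]
    mu = np.zeros(ref.shape)
    mu[labels.labels == 1] = coeffs.soft
    bone_sel = labels.labels == 2
    if mode == "fix":
        mu[bone_sel] = coeffs.bone
    else:
        if not r2s.same_grid(ref):
            raise ValueError("R2* map grid mismatch")
        mu[bone_sel] = calib(r2s.data[bone_sel])
    out = Volume(mu, ref.spacing, ref.origin, "mu_cm_inv")
    if smoothing_fwhm_mm > 0:
        out = gaussian_smooth(out, smoothing_fwhm_mm)
    if coverage_mask is not None and fallback is not None:
        if not fallback.same_grid(out):
            raise ValueError("fallback grid mismatch")
        outside = coverage_mask.data <= 0
        data = out.data.copy()
        data[outside] = fallback.data[outside]
        out = out.with_data(data)
    return out


def make_mc_ac_map(labels6: LabelMask, coeffs: ACCoefficients | None = None,
                   smoothing_fwhm_mm: float = 2.0) -> Volume:
    """Six-class (mcAC) map: per-class constants, then 2-mm smoothing."""
    coeffs = coeffs or ACCoefficients()
    mu = np.zeros(labels6.labels.shape)
    for value, name in labels6.label_table.items():
        if not hasattr(coeffs, name):
            raise ValueError(f"unknown label {name!r}")
        mu[labels6.labels == value] = coeffs.for_class(name)
    out = Volume(mu, labels6.spacing, labels6.origin, "mu_cm_inv")
    if smoothing_fwhm_mm > 0:
        out = gaussian_smooth(out, smoothing_fwhm_mm)
    return out


def reference_ac_from_labels(truth: LabelMask,
                             coeffs: ACCoefficients | None = None) -> Volume:
    """Piecewise-constant reference map: bone 0.151, soft 0.100, air 0.

    Brain classes (GM/WM/CSF) fold into soft tissue; no smoothing.
    """
    coeffs = coeffs or ACCoefficients()
    fold = {"air": coeffs.air, "soft": coeffs.soft, "bone": coeffs.bone,
            "gm": coeffs.soft, "wm": coeffs.soft, "csf": coeffs.soft}
    mu = np.zeros(truth.labels.shape)
    for value, name in truth.label_table.items():
        if name not in fold:
            raise ValueError(f"unknown label {name!r}")
        mu[truth.labels == value] = fold[name]
    return Volume(mu, truth.spacing, truth.origin, "mu_cm_inv")


def hu_to_mu(ct: Volume, breakpoint_hu: float = 0.0,
             slope_high: float = 6.4e-5) -> Volume:
    """Bilinear HU -> 511 keV mu conversion.

    Below the breakpoint: mu = 0.096 * (HU + 1000) / 1000 (anchored at air
    -1000 HU -> 0 and water 0 HU -> 0.096 cm^-1). Above it, a bone slope in
    cm^-1 per HU. Negative mu is clamped to 0.
    """
    if ct.units != "HU":
        raise ValueError("hu_to_mu expects a volume in HU")
    hu = np.asarray(ct.data, dtype=np.float64)
    low = 0.096 * (hu + 1000.0) / 1000.0
    base = 0.096 * (breakpoint_hu + 1000.0) / 1000.0
    high = base + slope_high * (hu - breakpoint_hu)
    mu = np.where(hu <= breakpoint_hu, low, high)
    return Volume(np.maximum(mu, 0.0), ct.spacing, ct.origin, "mu_cm_inv")


def classify_ct(ct: Volume, air_hu: float = -500.0,
                bone_hu: float = 300.0) -> LabelMask:
    """CT classification: strictly below -500 HU air, above 300 HU bone."""
    if ct.units != "HU":
        raise ValueError("classify_ct expects a volume in HU")
    labels = np.ones(ct.shape, dtype=np.int16)
    labels[ct.data < air_hu] = 0
    labels[ct.data > bone_hu] = 2
    return LabelMask(labels, {0: "air", 1: "soft", 2: "bone"},
                     ct.spacing, ct.origin)


def classify_vendor_ute(ac: Volume, eps: float = 1e-6) -> LabelMask:
    """Vendor-map rule: mu == 0.151 cm^-1 -> bone, mu == 0 -> air."""
    if ac.units != "mu_cm_inv":
        raise ValueError("classify_vendor_ute expects a mu map (cm^-1)")
    mu = np.asarray(ac.data, dtype=np.float64)
    labels = np.ones(ac.shape, dtype=np.int16)
    labels[np.abs(mu) < eps] = 0
    labels[np.abs(mu - 0.151) < eps] = 2
    return LabelMask(labels, {0: "air", 1: "soft", 2: "bone"},
                     ac.spacing, ac.origin)
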