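"""Volume data model, NIfTI-1 I/O, resampling and Gaussian smoothing.

All stages of the pipeline exchange :class:`Volume` objects — 3-D scalar
fields with voxel spacing in mm, a world origin, and a units tag that
distinguishes raw MR intensity, Hounsfield units, 511 keV linear attenuation
coefficients (cm^-1), R2* relaxation rates (1/ms), probabilities and
activity. Internal processing assumes a fixed RAS-like axis order; files in
other orientations are reoriented on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

UNITS = ("intensity", "HU", "mu_cm_inv", "r2star_per_ms", "probability", "activity")

#: NIfTI extension code used to carry the units tag ("comment" ecode).
_UNITS_ECODE = 6
_UNITS_KEY = "sute_ac_units"

#: FWHM -> Gaussian sigma conversion, 1 / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3-D scalar field on an axis-aligned grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : 3-tuple of positive floats, mm per axis
    origin : 3-tuple of floats, world position (mm) of voxel (0, 0, 0)
    units : one of :data:`UNITS`
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing).ravel())
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in np.asarray(self.origin).ravel())
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 components")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.data.size:
            if self.units == "probability":
                lo, hi = np.nanmin(self.data), np.nanmax(self.data)
                if lo < -1e-9 or hi > 1 + 1e-9:
                    raise ValueError(f"probability volume outside [0, 1]: [{lo}, {hi}]")
            elif self.units == "mu_cm_inv":
                lo = np.nanmin(self.data)
                if lo < -1e-12:
                    raise ValueError(f"mu_cm_inv volume has negative values (min {lo})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (axis-aligned RAS)."""
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.spacing
        a[:3, 3] = self.origin
        return a

    def with_data(self, data: np.ndarray, units: str | None = None) -> "Volume":
        """New Volume on the same grid with different voxel values."""
        return Volume(np.asarray(data), self.spacing, self.origin,
                      self.units if units is None else units)

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))


@dataclass
class LabelMask:
    """Integer label grid with a label -> tissue-name table."""

    labels: np.ndarray
    label_table: dict[int, str]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMask labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integers")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"label_table does not cover labels {sorted(missing)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to ``name``."""
        values = [v for v, n in self.label_table.items() if n == name]
        out = np.zeros(self.labels.shape, dtype=bool)
        for v in values:
            out |= self.labels == v
        return out

    def names(self) -> set[str]:
        return set(self.label_table.values())


def read_volume(path: str | Path, units: str | None = None) -> Volume:
    """Read a single 3-D NIfTI-1 volume.

    The image is reoriented to the closest RAS-aligned orientation. A units
    tag written by :func:`write_volume` (NIfTI extension) takes precedence
    over the ``units`` hint; with neither, units default to ``"intensity"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    stored = _read_units_extension(img)
    if stored is not None:
        units = stored
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return Volume(data, spacing, origin, units or "intensity")


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 (float32), carrying the units tag."""
    if not np.all(np.isfinite(v.data)):
        raise ValueError("refusing to write volume with non-finite voxels")
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    payload = json.dumps({_UNITS_KEY: v.units}).encode()
    img.header.extensions.append(nib.nifti1.Nifti1Extension(_UNITS_ECODE, payload))
    nib.save(img, str(path))


def _read_units_extension(img) -> str | None:
    for ext in img.header.extensions:
        if ext.get_code() != _UNITS_ECODE:
            continue
        raw = ext.get_content()
        if isinstance(raw, bytes):
            raw = raw.rstrip(b"\x00").decode(errors="ignore")
        try:
            doc = json.loads(raw)
        except (json.JSONDecodeError, TypeError):
            continue
        if isinstance(doc, dict) and _UNITS_KEY in doc:
            return str(doc[_UNITS_KEY])
    return None


def resample_to(v: Volume, reference: Volume, transform: np.ndarray | None = None,
                interpolation: str = "trilinear") -> Volume:
    """Resample ``v`` onto the grid of ``reference``.

    ``transform`` is a 4x4 world-to-world affine mapping points of ``v`` into
    the reference world frame (identity when omitted). Out-of-field voxels
    are filled with 0. ``interpolation`` is ``"trilinear"`` or ``"nearest"``;
    nearest is meant for label-derived volumes.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be a 4x4 affine")
    det = np.linalg.det(transform[:3, :3])
    if abs(det) < 1e-12:
        raise ValueError("singular transform")
    if np.allclose(transform, np.eye(4)) and v.same_grid(reference):
        return Volume(v.data.copy(), v.spacing, v.origin, v.units)
    # output voxel -> ref world -> input world -> input voxel
    m = np.linalg.inv(v.affine) @ np.linalg.inv(transform) @ reference.affine
    order = 1 if interpolation == "trilinear" else 0
    out = ndimage.affine_transform(
        np.asarray(v.data, dtype=np.float64), m[:3, :3], offset=m[:3, 3],
        output_shape=reference.shape, order=order, mode="constant", cval=0.0)
    if v.units == "probability":
        out = np.clip(out, 0.0, 1.0)
    return Volume(out, reference.spacing, reference.origin, v.units)


def resample_labels(m: LabelMask, reference: Volume,
                    transform: np.ndarray | None = None) -> LabelMask:
    """Nearest-neighbour resampling of a LabelMask onto a reference grid."""
    src = Volume(m.labels.astype(np.float64), m.spacing, m.origin, "intensity")
    out = resample_to(src, reference, transform, interpolation="nearest")
    labels = np.rint(out.data).astype(m.labels.dtype)
    table = dict(m.label_table)
    table.setdefault(0, table.get(0, "air"))  # out-of-field fill
    return LabelMask(labels, table, reference.spacing, reference.origin)


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with the kernel width given as FWHM in mm.

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxels via the
    spacing. Boundaries use constant-0 padding: the physical background of an
    attenuation map is air (mu = 0).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in v.spacing]
    out = ndimage.gaussian_filter(np.asarray(v.data, dtype=np.float64),
                                  sigma_vox, mode="constant", cval=0.0)
    if v.units == "probability":
        out = np.clip(out, 0.0, 1.0)
    elif v.units == "mu_cm_inv":
        out = np.maximum(out, 0.0)
    return v.with_data(out)
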