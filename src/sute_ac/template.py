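"""UTE1 template and six-class tissue probability map (TPM) construction.

The template is the voxel-wise mean of aligned first-echo UTE images. Class
probability maps are built by averaging aligned per-subject masks (or
probabilities), then enforcing the unit-sum constraint. Air and bone are the
protected classes: where the per-voxel sum of all classes exceeds one, their
values are kept and the remaining tissues are rescaled; the same
multiplicative fill is applied where the sum falls short of one so that
probabilities always sum to unity.

Registration is pluggable — the builder consumes world-to-world transforms
computed elsewhere; the phantom workflow supplies known (identity)
transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import Volume, resample_to

CLASSES = ("air", "soft", "bone", "gm", "wm", "csf")
PROTECTED = frozenset({"air", "bone"})

_SUM_TOL = 1e-6


@dataclass
class TPMSet:
    """Per-class probability volumes on one grid, per-voxel sum 1."""

    maps: dict[str, Volume]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(CLASSES) - set(self.maps)
        if missing:
            raise ValueError(f"TPMSet missing classes {sorted(missing)}")
        ref = self.maps[CLASSES[0]]
        for name, m in self.maps.items():
            if not m.same_grid(ref):
                raise ValueError(f"TPM {name!r} not on the common grid")
            lo, hi = float(np.min(m.data)), float(np.max(m.data))
            if lo < -_SUM_TOL or hi > 1 + _SUM_TOL:
                raise ValueError(f"TPM {name!r} outside [0, 1]: [{lo}, {hi}]")
        total = self.sum_map()
        err = float(np.max(np.abs(total - 1.0)))
        if err > _SUM_TOL:
            raise ValueError(f"per-voxel TPM sum deviates from 1 by {err:.2e}")

    def sum_map(self) -> np.ndarray:
        return np.sum([self.maps[c].data for c in CLASSES], axis=0)

    def stack(self) -> np.ndarray:
        """(K, nx, ny, nz) array in canonical class order."""
        return np.stack([self.maps[c].data for c in CLASSES])

    @property
    def grid(self) -> Volume:
        return self.maps[CLASSES[0]]

    def __getitem__(self, name: str) -> Volume:
        return self.maps[name]


def _align(vols, transforms, reference: Volume) -> list[np.ndarray]:
    if transforms is None:
        transforms = [None] * len(vols)
    if len(transforms) != len(vols):
        raise ValueError("transforms count does not match image count")
    return [resample_to(v, reference, t, interpolation="trilinear").data
            for v, t in zip(vols, transforms)]


def build_template(images: list[Volume], transforms=None,
                   reference: Volume | None = None) -> Volume:
    """Voxel-wise arithmetic mean of aligned first-echo images."""
    if len(images) < 2:
        raise ValueError("template construction needs at least 2 images")
    ref = reference if reference is not None else images[0]
    aligned = _align(images, transforms, ref)
    return ref.with_data(np.mean(aligned, axis=0), units="intensity")


def average_masks(masks: list[Volume], transforms=None,
                  reference: Volume | None = None) -> Volume:
    """Align (trilinear) then average probability masks; output in [0, 1]."""
    if not masks:
        raise ValueError("no masks given")
    for m in masks:
        if np.min(m.data) < 0 or np.max(m.data) > 1 + _SUM_TOL:
            raise ValueError("mask values outside [0, 1]")
    ref = reference if reference is not None else masks[0]
    aligned = _align(masks, transforms, ref)
    mean = np.clip(np.mean(aligned, axis=0), 0.0, 1.0)
    return ref.with_data(mean, units="probability")


def normalize_tpms(raw: dict[str, Volume], provenance: str = "") -> TPMSet:
    """Rescale classes per voxel so probabilities sum to 1.

    Voxels with zero total mass are assigned to air (outside-head background).
    """
    _check_classes(raw)
    stack = np.stack([np.asarray(raw[c].data, dtype=np.float64) for c in CLASSES])
    if np.min(stack) < 0:
        raise ValueError("negative class probabilities")
    total = stack.sum(axis=0)
    zero = total <= 0
    safe = np.where(zero, 1.0, total)
    stack = stack / safe
    stack[:, zero] = 0.0
    stack[CLASSES.index("air")][zero] = 1.0
    return _to_tpmset(stack, raw, provenance)


def renormalize_protected(raw: dict[str, Volume],
                          protected: frozenset = PROTECTED,
                          provenance: str = "") -> TPMSet:
    """Unit-sum normalization that leaves the protected classes untouched.

    Protected values are clipped to [0, 1] (with a warning) if needed; their
    per-voxel sum must not exceed 1 after clipping. Non-protected classes are
    multiplied by (1 - sum_protected) / sum_nonprotected so the total is
    exactly 1 — both where the raw sum exceeds 1 and where it falls short.
    Voxels with no non-protected mass put the deficit into the soft class.
    """
    _check_classes(raw)
    protected = frozenset(protected)
    unknown = protected - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown protected classes {sorted(unknown)}")
    stack = np.stack([np.asarray(raw[c].data, dtype=np.float64) for c in CLASSES])
    if np.min(stack) < 0:
        raise ValueError("negative class probabilities")
    pidx = [CLASSES.index(c) for c in sorted(protected)]
    nidx = [i for i in range(len(CLASSES)) if i not in pidx]

    if np.max(stack[pidx]) > 1 + _SUM_TOL:
        warnings.warn("protected class probabilities above 1 were clipped")
        stack[pidx] = np.clip(stack[pidx], 0.0, 1.0)
    psum = stack[pidx].sum(axis=0)
    if np.max(psum) > 1 + _SUM_TOL:
        raise ValueError("protected classes sum to more than 1 after clipping")
    psum = np.minimum(psum, 1.0)

    nsum = stack[nidx].sum(axis=0)
    residual = 1.0 - psum
    degenerate = nsum <= 0
    factor = np.where(degenerate, 0.0, residual / np.where(degenerate, 1.0, nsum))
    for i in nidx:
        stack[i] *= factor
    # no non-protected mass to rescale: give the remainder to soft tissue
    soft = CLASSES.index("soft")
    stack[soft][degenerate] += residual[degenerate]
    return _to_tpmset(np.clip(stack, 0.0, 1.0), raw, provenance)


def _check_classes(raw: dict[str, Volume]) -> None:
    missing = set(CLASSES) - set(raw)
    if missing:
        raise ValueError(f"missing classes {sorted(missing)}")
    ref = raw[CLASSES[0]]
    for c in CLASSES:
        if not raw[c].same_grid(ref):
            raise ValueError(f"class {c!r} not on the common grid")


def _to_tpmset(stack: np.ndarray, raw: dict[str, Volume],
               provenance: str) -> TPMSet:
    ref = raw[CLASSES[0]]
    maps = {c: Volume(stack[i], ref.spacing, ref.origin, "probability")
            for i, c in enumerate(CLASSES)}
    return TPMSet(maps, provenance)
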