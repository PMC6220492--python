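"""Synthetic dual-echo UTE head phantoms with ground truth.

The generator emulates what the attenuation-correction method needs from a
real acquisition: a head with a scalp soft-tissue layer, a closed skull
shell, a brain with a grey-matter rind, white-matter core and CSF
ventricles, and air-filled sinus cavities. From per-tissue proton density
and R2* it simulates the two UTE echoes with the mono-exponential decay
model I(TE) = PD * exp(-TE * R2*), the same model the R2* mapping inverts.
Cortical bone gets a high R2* (default 2.0 /ms) so that the second echo
(TE2 = 2.46 ms) suppresses bone signal while the first (TE1 = 0.07 ms)
retains it — the UTE contrast mechanism the segmentation relies on.

Ground truth (labels, PD, R2*, true 511 keV mu-map, FDG-like activity,
region atlas, head mask) plays the role of the manual segmentation the
method is evaluated against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import LabelMask, Volume

TISSUES = ("air", "soft", "bone", "gm", "wm", "csf")
LABELS = {"air": 0, "soft": 1, "bone": 2, "gm": 3, "wm": 4, "csf": 5}
LABEL_TABLE = {v: k for k, v in LABELS.items()}

REGION_TABLE = {
    0: "background",
    1: "frontal",
    2: "parietal",
    3: "occipital",
    4: "cerebellum_like",
    5: "deep_central",
    6: "periventricular",
}


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue physical parameters.

    proton_density is in arbitrary MR intensity units, r2star in 1/ms,
    mu_true in cm^-1 at 511 keV, activity in arbitrary units.
    """

    name: str
    proton_density: float
    r2star: float
    mu_true: float
    activity: float

    def __post_init__(self) -> None:
        if self.r2star < 0 or self.mu_true < 0 or self.activity < 0:
            raise ValueError(f"{self.name}: r2star/mu/activity must be >= 0")
        if self.name == "air" and (self.proton_density != 0 or self.mu_true != 0
                                   or self.activity != 0):
            raise ValueError("air must have zero PD, mu and activity")
        if self.proton_density < 0:
            raise ValueError("proton_density must be >= 0")


def default_tissues() -> dict[str, TissueParams]:
    """Default tissue table.

    mu values are the method's assigned coefficients (bone 0.151, soft 0.100,
    GM/WM 0.099, CSF 0.096, air 0 cm^-1). R2* defaults (bone 2.0 /ms, soft
    tissues <= 0.03 /ms) give the bone-suppression contrast at the
    0.07/2.46 ms echo pair. FDG-like activity ratios GM:WM:CSF = 4:1:0.1.
    """
    return {
        "air": TissueParams("air", 0.0, 0.0, 0.0, 0.0),
        "soft": TissueParams("soft", 100.0, 0.02, 0.100, 0.0),
        "bone": TissueParams("bone", 40.0, 2.0, 0.151, 0.0),
        "gm": TissueParams("gm", 90.0, 0.025, 0.099, 4.0),
        "wm": TissueParams("wm", 80.0, 0.025, 0.099, 1.0),
        "csf": TissueParams("csf", 105.0, 0.005, 0.096, 0.1),
    }


@dataclass
class PhantomSpec:
    """Geometry and acquisition parameters of a synthetic head."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # x = left-right, y = posterior-anterior, z = inferior-superior (mm,
    # measured from the grid centre)
    head_semiaxes: tuple[float, float, float] = (70.0, 85.0, 78.0)
    # cranial vault: an offset ellipsoid shell; head tissue outside it is
    # scalp/face soft tissue, which hosts the air sinuses
    skull_center: tuple[float, float, float] = (0.0, 0.0, 10.0)
    skull_outer_semiaxes: tuple[float, float, float] = (60.0, 72.0, 62.0)
    skull_thickness_mm: float = 6.0
    gm_thickness_mm: float = 8.0
    ventricle_semiaxes: tuple[float, float, float] = (8.0, 20.0, 8.0)
    ventricle_centers: tuple = ((-12.0, -4.0, 16.0), (12.0, -4.0, 16.0))
    sinus_radius_mm: float = 9.0
    sinus_centers: tuple = ((-13.0, 55.0, -40.0), (13.0, 55.0, -40.0))
    tissues: dict[str, TissueParams] = field(default_factory=default_tissues)
    te1_ms: float = 0.07
    te2_ms: float = 2.46
    noise_sigma: float = 0.03       # fraction of soft-tissue echo-1 intensity
    noise_model: str = "rician"
    bias_amplitude: float = 0.0     # multiplicative bias field, 0 = off
    bias_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.skull_thickness_mm <= 0:
            raise ValueError("skull thickness must be positive")
        if min(self.skull_outer_semiaxes) <= self.skull_thickness_mm + self.gm_thickness_mm:
            raise ValueError("skull thicker than the vault semi-axis: no room for brain")
        for sa, c, ha in zip(self.skull_outer_semiaxes, self.skull_center,
                             self.head_semiaxes):
            if abs(c) + sa >= ha:
                raise ValueError("skull vault does not fit inside the head")
        for sa, n, sp in zip(self.head_semiaxes, self.shape, self.spacing):
            if sa >= n * sp / 2:
                raise ValueError("head does not fit inside the grid")


@dataclass
class PhantomBundle:
    """Ground truth plus simulated echoes for one synthetic subject."""

    spec: PhantomSpec
    labels: LabelMask
    pd_map: Volume
    r2star_map: Volume
    mu_true: Volume
    activity_map: Volume
    region_atlas: LabelMask
    head_mask: Volume
    echo1: Volume
    echo2: Volume

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.labels.mask("gm") | self.labels.mask("wm")
                | self.labels.mask("csf"))


def simulate_ute_echo(pd_map: Volume, r2star_map: Volume, te_ms: float) -> Volume:
    """Noiseless UTE echo: I(x) = PD(x) * exp(-te_ms * R2*(x))."""
    if te_ms <= 0:
        raise ValueError("te_ms must be positive")
    pd = np.asarray(pd_map.data, dtype=np.float64)
    if np.any(pd < 0):
        raise ValueError("negative proton density")
    r2s = np.asarray(r2star_map.data, dtype=np.float64)
    return pd_map.with_data(pd * np.exp(-te_ms * r2s), units="intensity")


def add_noise(v: Volume, sigma: float, model: str = "rician",
              seed: int = 0) -> Volume:
    """Add Gaussian or Rician (magnitude) noise of absolute scale ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return v.with_data(v.data.copy())
    rng = np.random.default_rng(seed)
    m = np.asarray(v.data, dtype=np.float64)
    if model == "gaussian":
        out = m + rng.normal(0.0, sigma, m.shape)
    elif model == "rician":
        n1 = rng.normal(0.0, sigma, m.shape)
        n2 = rng.normal(0.0, sigma, m.shape)
        out = np.sqrt((m + n1) ** 2 + n2 ** 2)
    else:
        raise ValueError(f"unknown noise model {model!r}")
    return v.with_data(out)


def _ellipsoid(xx, yy, zz, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
            + ((zz - cz) / az) ** 2) <= 1.0


def _world_grids(spec: PhantomSpec):
    coords = [(np.arange(n) - (n - 1) / 2.0) * s
              for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*coords, indexing="ij")


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    xx, yy, zz = _world_grids(spec)
    head = _ellipsoid(xx, yy, zz, (0, 0, 0), spec.head_semiaxes)
    a = np.array(spec.skull_outer_semiaxes, dtype=float)
    c = spec.skull_center
    skull_outer = _ellipsoid(xx, yy, zz, c, a)
    brain_outer = _ellipsoid(xx, yy, zz, c, a - spec.skull_thickness_mm)
    wm_outer = _ellipsoid(xx, yy, zz, c,
                          a - spec.skull_thickness_mm - spec.gm_thickness_mm)
    labels = np.zeros(spec.shape, dtype=np.int16)  # air
    labels[head] = LABELS["soft"]
    labels[skull_outer] = LABELS["bone"]
    labels[brain_outer] = LABELS["gm"]
    labels[wm_outer] = LABELS["wm"]
    for c in spec.ventricle_centers:
        labels[_ellipsoid(xx, yy, zz, c, spec.ventricle_semiaxes)] = LABELS["csf"]
    # sinus air cavities: carved only out of non-brain soft tissue so the
    # skull shell stays closed
    for c in spec.sinus_centers:
        sphere = _ellipsoid(xx, yy, zz, c, (spec.sinus_radius_mm,) * 3)
        labels[sphere & (labels == LABELS["soft"])] = LABELS["air"]
    return labels


def _build_atlas(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    xx, yy, zz = _world_grids(spec)
    brain = np.isin(labels, (LABELS["gm"], LABELS["wm"], LABELS["csf"]))
    ventricle = labels == LABELS["csf"]
    # periventricular: within 6 mm of the ventricles, excluding them
    it = max(1, int(round(6.0 / min(spec.spacing))))
    peri = ndimage.binary_dilation(ventricle, iterations=it) & ~ventricle & brain
    bz = spec.skull_center[2]
    atlas = np.zeros(spec.shape, dtype=np.int16)
    atlas[peri] = 6
    free = brain & (atlas == 0) & ~ventricle
    cereb = free & (zz < bz - 40.0) & (yy < 10.0)
    atlas[cereb] = 4
    free &= atlas == 0
    atlas[free & (yy > 35.0)] = 1                      # frontal
    free &= atlas == 0
    atlas[free & (yy < -35.0)] = 3                     # occipital
    free &= atlas == 0
    deep = free & (np.abs(xx) < 25.0) & (np.abs(yy) < 25.0) \
        & (np.abs(zz - (bz + 6.0)) < 22.0)
    atlas[deep] = 5
    free &= atlas == 0
    atlas[free & (zz > bz + 25.0)] = 2                 # parietal
    return atlas


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.bias_amplitude <= 0:
        return np.ones(spec.shape)
    xx, yy, zz = _world_grids(spec)
    scale = max(spec.head_semiaxes)
    u, v, w = xx / scale, yy / scale, zz / scale
    poly = np.zeros(spec.shape)
    for i in range(spec.bias_order + 1):
        for j in range(spec.bias_order + 1 - i):
            for k in range(spec.bias_order + 1 - i - j):
                if i == j == k == 0:
                    continue
                poly += rng.normal() * (u ** i) * (v ** j) * (w ** k)
    peak = np.max(np.abs(poly))
    if peak > 0:
        poly /= peak
    return 1.0 + spec.bias_amplitude * poly


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate a deterministic phantom bundle for a given spec/seed."""
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec)

    lut = {name: spec.tissues[name] for name in TISSUES}
    pd = np.zeros(spec.shape)
    r2s = np.zeros(spec.shape)
    mu = np.zeros(spec.shape)
    act = np.zeros(spec.shape)
    for name, idx in LABELS.items():
        sel = labels == idx
        pd[sel] = lut[name].proton_density
        r2s[sel] = lut[name].r2star
        mu[sel] = lut[name].mu_true
        act[sel] = lut[name].activity

    sp, orig = spec.spacing, tuple(-(n - 1) / 2.0 * s
                                   for n, s in zip(spec.shape, spec.spacing))
    vol = lambda d, u: Volume(d, sp, orig, u)  # noqa: E731
    pd_map = vol(pd, "intensity")
    r2s_map = vol(r2s, "r2star_per_ms")

    bias = _bias_field(spec, rng)
    e1 = simulate_ute_echo(pd_map, r2s_map, spec.te1_ms)
    e2 = simulate_ute_echo(pd_map, r2s_map, spec.te2_ms)
    e1 = e1.with_data(e1.data * bias)
    e2 = e2.with_data(e2.data * bias)
    if spec.noise_sigma > 0:
        soft = lut["soft"]
        sigma_abs = spec.noise_sigma * soft.proton_density * np.exp(
            -spec.te1_ms * soft.r2star)
        s1, s2 = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
        e1 = add_noise(e1, sigma_abs, spec.noise_model, seed=s1)
        e2 = add_noise(e2, sigma_abs, spec.noise_model, seed=s2)

    xx, yy, zz = _world_grids(spec)
    head = _ellipsoid(xx, yy, zz, (0, 0, 0), spec.head_semiaxes)

    return PhantomBundle(
        spec=spec,
        labels=LabelMask(labels, dict(LABEL_TABLE), sp, orig),
        pd_map=pd_map,
        r2star_map=r2s_map,
        mu_true=vol(mu, "mu_cm_inv"),
        activity_map=vol(act, "activity"),
        region_atlas=LabelMask(_build_atlas(spec, labels), dict(REGION_TABLE), sp, orig),
        head_mask=vol(head.astype(np.float64), "probability"),
        echo1=e1,
        echo2=e2,
    )


def jittered_cohort(base: PhantomSpec, n_subjects: int = 5,
                    seed: int = 0, geometry_jitter: float = 0.015) -> list[PhantomSpec]:
    """Specs for a cohort of subjects with slightly perturbed head geometry.

    Semi-axes are scaled by ~N(1, geometry_jitter) and ventricles shifted by
    up to 1 mm; the cohort stands in for the five template subjects, assumed
    pre-aligned (identity transforms) since registration is out of scope.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        f = np.clip(rng.normal(1.0, geometry_jitter, 3), 0.95, 1.05)
        shift = rng.uniform(-1.0, 1.0, 3)
        specs.append(replace(
            base,
            head_semiaxes=tuple(a * fi for a, fi in zip(base.head_semiaxes, f)),
            skull_outer_semiaxes=tuple(a * fi for a, fi in
                                       zip(base.skull_outer_semiaxes, f)),
            ventricle_centers=tuple(tuple(c + shift) for c in
                                    np.asarray(base.ventricle_centers)),
            seed=int(rng.integers(2 ** 31)),
        ))
    return specs
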