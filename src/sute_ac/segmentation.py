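"""Gaussian-mixture tissue classification with spatial priors.

The first-echo UTE image is classified into {air, soft, bone, GM, WM, CSF}
by expectation-maximization on a Gaussian intensity mixture in which each
voxel's class weights are its tissue-probability-map (TPM) priors:

    posterior_k(x)  propto  prior_k(x) * sum_j w_kj N(I(x); mu_kj, s2_kj)

Only the first echo enters the likelihood; the second echo is used solely
for R2* mapping. Hard labels follow the thresholded rules: air posterior
above 0.1 -> air, then bone posterior above 0.2 -> bone (bone overrides air
on conflict: missing skull is the costlier PET error), remainder -> soft.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .template import CLASSES, TPMSet
from .volume import LabelMask, Volume

HARD_LABELS = {0: "air", 1: "soft", 2: "bone"}

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GMMConfig:
    gaussians_per_class: int = 1
    max_iterations: int = 100
    loglik_tolerance: float = 1e-6     # relative log-likelihood change
    variance_floor: float = 1e-4       # fraction of the global intensity variance
    bias_correction: str = "none"      # "none" | "polynomial"
    bias_order: int = 3

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.loglik_tolerance <= 0 or self.variance_floor <= 0:
            raise ValueError("tolerance and variance_floor must be positive")
        if self.gaussians_per_class < 1:
            raise ValueError("gaussians_per_class must be >= 1")
        if self.bias_correction not in ("none", "polynomial"):
            raise ValueError("bias_correction must be 'none' or 'polynomial'")


@dataclass
class GaussianComponent:
    class_name: str
    weight: float
    mean: float
    variance: float


@dataclass
class SegmentationResult:
    posteriors: dict[str, Volume]
    class_params: list[GaussianComponent]
    loglik_trace: np.ndarray
    classes: tuple[str, ...]
    bias_field: Volume | None = None

    def posterior_stack(self) -> np.ndarray:
        return np.stack([self.posteriors[c].data for c in self.classes])


def em_fit(x: np.ndarray, priors: np.ndarray, config: GMMConfig | None = None,
           init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None):
    """EM for a prior-weighted Gaussian mixture on flat data.

    Parameters
    ----------
    x : (N,) intensities
    priors : (N, K) per-sample class priors (rows need not be normalized)
    init : optional (means, variances, weights), each (K, J); by default
        means/variances are initialized from prior-weighted moments, with a
        quantile fallback when the priors are uninformative (coincident
        means).

    Returns
    -------
    means, variances, weights : (K, J) arrays
    resp : (N, K) class posteriors (summed over the J components)
    trace : per-iteration log-likelihood (non-decreasing)
    """
    config = config or GMMConfig()
    x = np.asarray(x, dtype=np.float64).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities")
    priors = np.asarray(priors, dtype=np.float64)
    if priors.ndim != 2 or priors.shape[0] != x.size:
        raise ValueError("priors must be (N, K)")
    n, k = priors.shape
    j = config.gaussians_per_class
    floor = config.variance_floor * max(np.var(x), 1e-30)

    if init is not None:
        means, variances, weights = (np.array(a, dtype=np.float64).reshape(k, j)
                                     for a in init)
    else:
        means, variances = _moment_init(x, priors, j)
        weights = np.full((k, j), 1.0 / j)
    variances = np.maximum(variances, floor)

    log_prior = np.log(np.maximum(priors, 0.0), where=priors > 0,
                       out=np.full_like(priors, -np.inf))
    trace = []
    prev = -np.inf
    resp_class = None
    for _ in range(config.max_iterations):
        # E-step: log joint over (class, component)
        log_joint = (log_prior[:, :, None]
                     + np.log(np.maximum(weights, 1e-300))[None, :, :]
                     - 0.5 * (_LOG_2PI + np.log(variances))[None, :, :]
                     - 0.5 * (x[:, None, None] - means[None, :, :]) ** 2
                     / variances[None, :, :])
        flat = log_joint.reshape(n, k * j)
        log_norm = logsumexp(flat, axis=1)
        ll = float(np.sum(log_norm))
        trace.append(ll)
        resp = np.exp(flat - log_norm[:, None]).reshape(n, k, j)
        resp_class = resp.sum(axis=2)
        if prev > -np.inf and abs(ll - prev) < config.loglik_tolerance * abs(prev):
            break
        prev = ll
        # M-step
        nk = resp.sum(axis=0)                      # (K, J)
        safe = np.maximum(nk, 1e-12)
        means = np.einsum("nkj,n->kj", resp, x) / safe
        variances = np.einsum("nkj,n->kj", resp,
                              x ** 2) / safe - means ** 2
        variances = np.maximum(variances, floor)
        class_tot = np.maximum(nk.sum(axis=1, keepdims=True), 1e-12)
        weights = nk / class_tot
    return means, variances, weights, resp_class, np.asarray(trace)


def _moment_init(x: np.ndarray, priors: np.ndarray, j: int):
    """Prior-weighted mean/variance init with a quantile fallback."""
    n, k = priors.shape
    wsum = np.maximum(priors.sum(axis=0), 1e-12)
    mu = priors.T @ x / wsum
    var = priors.T @ (x ** 2) / wsum - mu ** 2
    spread = np.ptp(x) if np.ptp(x) > 0 else 1.0
    # uninformative priors give coincident class means: fall back to
    # evenly spaced quantiles so EM can break the symmetry
    if k > 1 and np.max(mu) - np.min(mu) < 1e-6 * spread:
        mu = np.quantile(x, (np.arange(k) + 0.5) / k)
        var = np.full(k, np.var(x) / k)
    means = np.repeat(mu[:, None], j, axis=1)
    variances = np.repeat(np.maximum(var, 1e-12)[:, None], j, axis=1)
    if j > 1:  # spread components within a class
        offsets = np.linspace(-0.5, 0.5, j)[None, :] * np.sqrt(variances)
        means = means + offsets
    return means, variances


def _polynomial_design(shape, order: int, mask: np.ndarray) -> np.ndarray:
    coords = [(np.arange(s) - (s - 1) / 2.0) / max(s / 2.0, 1.0) for s in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(order + 1):
        for jj in range(order + 1 - i):
            for kk in range(order + 1 - i - jj):
                cols.append((xx ** i * yy ** jj * zz ** kk)[mask])
    return np.stack(cols, axis=1)


def fit_gmm_with_priors(image: Volume, priors: TPMSet,
                        mask: Volume | np.ndarray | None = None,
                        config: GMMConfig | None = None) -> SegmentationResult:
    """Segment an intensity volume using TPM spatial priors.

    Classes with zero prior mass inside the mask are dropped with a warning
    and receive an all-zero posterior. With ``bias_correction="polynomial"``
    a multiplicative low-order polynomial field is re-estimated between EM
    passes by log-domain least squares against the class-predicted
    intensities.
    """
    config = config or GMMConfig()
    if not image.same_grid(priors.grid):
        raise ValueError("image and priors are not on one grid")
    if mask is None:
        sel = np.ones(image.shape, dtype=bool)
    else:
        m = mask.data if isinstance(mask, Volume) else np.asarray(mask)
        sel = m > 0.5
    if not np.any(sel):
        raise ValueError("empty mask")
    x = np.asarray(image.data, dtype=np.float64)[sel]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities")

    stack = priors.stack()
    pm = stack[:, sel].T                                  # (N, K_all)
    keep = []
    for i, c in enumerate(CLASSES):
        if pm[:, i].sum() > 0:
            keep.append(i)
        else:
            warnings.warn(f"class {c!r} has zero prior mass in the mask; dropped")
    active = tuple(CLASSES[i] for i in keep)
    pm = pm[:, keep]

    bias_log = np.zeros(x.shape)
    design = None
    if config.bias_correction == "polynomial":
        design = _polynomial_design(image.shape, config.bias_order, sel)

    corrected = x
    trace_all = []
    n_outer = 1 if config.bias_correction == "none" else 5
    inner = config.max_iterations if n_outer == 1 else max(
        1, config.max_iterations // n_outer)
    inner_cfg = GMMConfig(config.gaussians_per_class, inner,
                          config.loglik_tolerance, config.variance_floor)
    means = variances = weights = resp = None
    for outer in range(n_outer):
        init = None if means is None else (means, variances, weights)
        means, variances, weights, resp, trace = em_fit(
            corrected, pm, inner_cfg, init=init)
        trace_all.extend(trace.tolist())
        if config.bias_correction == "none":
            break
        # predicted intensity per voxel from current posteriors
        class_mean = (weights * means).sum(axis=1)
        pred = resp @ class_mean
        ok = (corrected > 0) & (pred > 0)
        if ok.sum() < design.shape[1]:
            break
        target = np.log(x[ok]) - np.log(pred[ok])
        coef, *_ = np.linalg.lstsq(design[ok], target, rcond=None)
        bias_log = design @ coef
        bias_log -= bias_log.mean()          # fix the overall scale
        corrected = x * np.exp(-bias_log)

    posteriors = {}
    for c in CLASSES:
        vol = np.zeros(image.shape)
        if c in active:
            vol[sel] = resp[:, active.index(c)]
        posteriors[c] = Volume(np.clip(vol, 0.0, 1.0), image.spacing,
                               image.origin, "probability")

    params = [GaussianComponent(active[i], float(weights[i, jj]),
                                float(means[i, jj]), float(variances[i, jj]))
              for i in range(len(active)) for jj in range(weights.shape[1])]
    bias_vol = None
    if config.bias_correction == "polynomial":
        b = np.ones(image.shape)
        b[sel] = np.exp(bias_log)
        bias_vol = Volume(b, image.spacing, image.origin, "intensity")
    return SegmentationResult(posteriors, params, np.asarray(trace_all),
                              CLASSES, bias_vol)


def hard_label(result: SegmentationResult, air_threshold: float = 0.1,
               bone_threshold: float = 0.2,
               bone_overrides: bool = True) -> LabelMask:
    """Threshold posteriors into {air, soft, bone}.

    Air posterior above ``air_threshold`` -> air; bone posterior above
    ``bone_threshold`` -> bone. By default bone wins where both rules fire.
    """
    for t in (air_threshold, bone_threshold):
        if not 0 < t < 1:
            raise ValueError("thresholds must lie in (0, 1)")
    air = result.posteriors["air"].data
    bone = result.posteriors["bone"].data
    labels = np.ones(air.shape, dtype=np.int16)           # soft
    if bone_overrides:
        labels[air > air_threshold] = 0
        labels[bone > bone_threshold] = 2
    else:
        labels[bone > bone_threshold] = 2
        labels[air > air_threshold] = 0
    ref = result.posteriors["air"]
    return LabelMask(labels, dict(HARD_LABELS), ref.spacing, ref.origin)


def hard_label_six(result: SegmentationResult, air_threshold: float = 0.1,
                   bone_threshold: float = 0.2) -> LabelMask:
    """Six-class labels: thresholded air/bone, argmax over the brain/soft
    classes elsewhere. Feeds the multi-compartment AC map."""
    three = hard_label(result, air_threshold, bone_threshold)
    rest_classes = ("soft", "gm", "wm", "csf")
    rest = np.stack([result.posteriors[c].data for c in rest_classes])
    arg = np.argmax(rest, axis=0)
    from .phantom import LABELS, LABEL_TABLE  # canonical 6-class coding
    labels = np.zeros(three.labels.shape, dtype=np.int16)
    for i, c in enumerate(rest_classes):
        labels[arg == i] = LABELS[c]
    labels[three.labels == 0] = LABELS["air"]
    labels[three.labels == 2] = LABELS["bone"]
    return LabelMask(labels, dict(LABEL_TABLE), three.spacing, three.origin)
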