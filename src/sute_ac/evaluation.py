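"""Quantitative comparison of segmentations, attenuation maps and PET images.

Implements tissue-wise Dice / false-positive / false-negative rates,
Diff/AbsDiff statistics between attenuation maps, voxel-wise relative-error
(RE%) maps with regional summaries, the 150-bin SVD representative
histogram, and Mann-Whitney U tests (exact enumeration for small samples,
tie-corrected normal approximation otherwise).

Dice uses the standard sum denominator 2|A n B| / (|A| + |B|); the literal
union-denominator variant (which evaluates to 2 for identical masks) is
exposed as :func:`dice_as_printed` for audit. The RE% map follows
R = 100 * (ref - x) / ref, so a test image *below* the reference gives a
positive R; tabulated per-method biases are conventionally reported with
the opposite orientation (x - ref), which callers obtain by negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .volume import LabelMask, Volume


def _as_bool(a) -> np.ndarray:
    arr = a.data if isinstance(a, Volume) else np.asarray(a)
    return arr > 0.5 if arr.dtype != bool else arr


def dice(a, b, region=None) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    if region is not None:
        r = _as_bool(region)
        a, b = a & r, b & r
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_as_printed(a, b, region=None) -> float:
    """Literal union-denominator variant: 2|A n B| / |A u B|."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    if region is not None:
        r = _as_bool(region)
        a, b = a & r, b & r
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / union


def fp_fn_rates(pred, ref, region=None) -> tuple[float, float]:
    """False-positive and false-negative rates of a binary segmentation.

    fp = |pred \\ ref| / |pred| (fraction of predicted positives that are
    false), fn = |ref \\ pred| / |ref| (fraction of reference positives
    missed); each 0 when its denominator is empty.
    """
    pred, ref = _as_bool(pred), _as_bool(ref)
    if pred.shape != ref.shape:
        raise ValueError("mask grids differ")
    if region is not None:
        r = _as_bool(region)
        pred, ref = pred & r, ref & r
    npred, nref = int(pred.sum()), int(ref.sum())
    fp = int((pred & ~ref).sum()) / npred if npred else 0.0
    fn = int((ref & ~pred).sum()) / nref if nref else 0.0
    return fp, fn


def diff_stats(ac_a: Volume, ac_b: Volume, head_mask) -> tuple[float, float, float, float]:
    """(mean, sd) of a-b and |a-b| within the head mask."""
    if ac_a.shape != ac_b.shape:
        raise ValueError("map grids differ")
    sel = _as_bool(head_mask)
    if not np.any(sel):
        raise ValueError("empty head mask")
    d = np.asarray(ac_a.data, dtype=np.float64)[sel] - np.asarray(
        ac_b.data, dtype=np.float64)[sel]
    return (float(d.mean()), float(d.std()),
            float(np.abs(d).mean()), float(np.abs(d).std()))


def relative_error_map(pet_ref: Volume, pet_x: Volume, mask,
                       floor_frac: float = 1e-6) -> Volume:
    """Voxel-wise RE% map R = 100 * (ref - x) / ref inside the mask.

    Voxels outside the mask, and voxels whose reference value falls below
    ``floor_frac`` times the in-mask mean reference, are undefined (NaN).
    """
    if pet_ref.shape != pet_x.shape:
        raise ValueError("image grids differ")
    sel = _as_bool(mask)
    ref = np.asarray(pet_ref.data, dtype=np.float64)
    x = np.asarray(pet_x.data, dtype=np.float64)
    if not np.any(sel):
        raise ValueError("empty mask")
    floor = floor_frac * ref[sel].mean()
    defined = sel & (ref > floor)
    if not np.any(defined):
        raise ValueError("no voxels remain after reference flooring")
    out = np.full(ref.shape, np.nan)
    out[defined] = 100.0 * (ref[defined] - x[defined]) / ref[defined]
    return Volume(out, pet_ref.spacing, pet_ref.origin, "intensity")


def regional_stats(re_map: Volume, atlas: LabelMask,
                   whole_mask=None) -> pd.DataFrame:
    """Per-region mean/SD of defined RE% voxels, plus a full-brain row.

    The full-brain row covers ``whole_mask`` when given, else the union of
    all nonzero atlas regions.
    """
    re = np.asarray(re_map.data, dtype=np.float64)
    rows = []
    union = np.zeros(re.shape, dtype=bool)
    for value, name in sorted(atlas.label_table.items()):
        if value == 0 or name == "background":
            continue
        sel = (atlas.labels == value) & np.isfinite(re)
        union |= sel
        if not np.any(sel):
            raise ValueError(f"region {name!r} has no defined voxels")
        rows.append((name, int(sel.sum()), float(re[sel].mean()),
                     float(re[sel].std())))
    whole = _as_bool(whole_mask) & np.isfinite(re) if whole_mask is not None else union
    rows.insert(0, ("full_brain", int(whole.sum()),
                    float(re[whole].mean()), float(re[whole].std())))
    return pd.DataFrame(rows, columns=["region", "n_voxels", "mean", "sd"])


def representative_histogram(images: list[Volume], masks: list,
                             n_bins: int = 150):
    """Most-representative intensity histogram across subjects via SVD.

    Each subject's histogram uses ``n_bins`` bins over its own masked
    intensity range (bin width fixed among methods, varying across
    subjects). The subjects-by-bins matrix is decomposed by SVD; the
    representative curve is the leading right-singular vector, sign-fixed to
    be non-negative-dominant and scaled by the leading singular value over
    sqrt(n_subjects).

    Returns (list of per-subject bin edges, representative curve).
    """
    if len(images) < 2:
        raise ValueError("need at least 2 subjects")
    if len(masks) != len(images):
        raise ValueError("one mask per image required")
    hists, edges = [], []
    for img, m in zip(images, masks):
        vals = np.asarray(img.data, dtype=np.float64)[_as_bool(m)]
        if vals.size == 0:
            raise ValueError("empty mask")
        h, e = np.histogram(vals, bins=n_bins)
        hists.append(h.astype(np.float64))
        edges.append(e)
    matrix = np.stack(hists)
    _, s, vt = np.linalg.svd(matrix, full_matrices=False)
    v = vt[0]
    if v.sum() < 0:
        v = -v
    rep = v * s[0] / np.sqrt(len(images))
    return edges, rep


def _u_statistic(ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(sample_a, sample_b,
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test (U of the first sample).

    Exact enumeration of all group assignments (ties handled with mid-ranks)
    when the combined sample size is at most 16; tie-corrected normal
    approximation with continuity correction otherwise. The two-sided exact
    p is 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(a.size), a.size)
    n = pooled.size
    if n <= 16:
        us = np.fromiter(
            (_u_statistic(ranks, idx, a.size)
             for idx in combinations(range(n), a.size)),
            dtype=np.float64)
        tol = 1e-9
        p_le = np.mean(us <= u_obs + tol)
        p_ge = np.mean(us >= u_obs - tol)
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
        return u_obs, float(p)
    res = stats.mannwhitneyu(a, b, alternative=alternative,
                             method="asymptotic", use_continuity=True)
    return u_obs, float(res.pvalue)
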