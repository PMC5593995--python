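"""CSF extraction and volumetry from T2-like MR volumes.

The pipeline follows the volumetry procedure of the monitoring study:
intensity rescaling and brain masking, fuzzy c-means clustering with a
Markov-random-field-style spatial regularizer, selection of the
hyperintense (CSF) class, masking with a prepared CSF template, and
voxel-counting volumetry.

The segmentation objective is

    J(U, V) = sum_i sum_k u_ik^m (x_i - v_k)^2
              + beta * s2 * sum_i sum_k u_ik^m mean_{j in N(i)} (1 - u_jk)

i.e. the standard fuzzy c-means data term plus a neighborhood penalty
that charges membership in class k at voxel i by how little its
neighbors belong to k.  The disagreement is averaged over the
neighborhood and scaled by ``s2``, the membership-weighted mean
within-class squared deviation, so ``beta`` is dimensionless: at
``beta = 1`` full neighborhood disagreement costs as much as one
typical within-class deviation, regardless of the intensity scale.
Minimization alternates the closed-form membership update (with the
neighborhood term and ``s2`` refreshed from the previous memberships,
ICM-style) and the usual centroid update, which the penalty term does
not involve.  With ``mrf_beta = 0`` the iteration is exactly plain
fuzzy c-means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label

from .volume import LabelMap, MRVolume, voxel_volume_mm3

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "FuzzyMembership",
    "CSFQuantification",
    "SegmentationPipelineResult",
    "preprocess",
    "fcm_mrf_segment",
    "select_csf_class",
    "apply_template",
    "quantify_volume",
    "segment_pipeline",
]

#: Label value for voxels outside the brain mask in segmentation outputs.
OUTSIDE_LABEL = 255


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the FCM+MRF segmenter.

    Defaults: four tissue classes (WM, GM, blood, CSF — background is
    removed by the brain mask), fuzzifier m=2, coupling beta=0.5 on a
    6-connected neighborhood, centroid tolerance 1e-4.
    """

    n_classes: int = 4
    fuzzifier: float = 2.0
    mrf_beta: float = 0.5
    neighborhood: int = 6
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.mrf_beta < 0:
            raise ValueError("mrf_beta must be >= 0")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass
class FuzzyMembership:
    """Soft memberships over K intensity classes on a brain-masked grid.

    ``membership`` has shape (K, *grid); memberships are zero outside
    the mask and sum to one (tol 1e-6) inside.  Centroids are sorted in
    ascending intensity, so class K-1 is always the brightest
    (CSF-like) class.
    """

    membership: np.ndarray
    centroids: np.ndarray
    mask: np.ndarray
    config: SegmentationConfig
    objective_trace: np.ndarray
    converged: bool

    @property
    def n_classes(self) -> int:
        return self.centroids.size


@dataclass(frozen=True)
class CSFQuantification:
    """Voxel-counting volumetry of a binary mask."""

    voxel_count: int
    voxel_volume_mm3: float
    volume_ml: float

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3


def preprocess(vol: MRVolume) -> MRVolume:
    """Rescale intensities to [0, 1] and attach a brain mask.

    The mask is the largest connected component above an Otsu
    threshold; the rescaling is affine, hence monotone.
    """
    x = vol.intensity
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("volume is constant; no foreground threshold exists")
    x = (x - lo) / (hi - lo)
    thr = threshold_otsu(x)
    fg = x > thr
    if not fg.any():
        raise ValueError("no voxels above the Otsu threshold")
    comps, n = cc_label(fg, return_num=True)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    mask = comps == int(np.argmax(sizes))
    return MRVolume(intensity=x, spacing=vol.spacing, mask=mask)


def _neighbor_sum(volume: np.ndarray, neighborhood: int) -> np.ndarray:
    """Sum of each voxel's neighbors (excluding itself)."""
    if neighborhood == 6:
        out = np.zeros_like(volume)
        k = np.array([1.0, 0.0, 1.0])
        for ax in range(3):
            out += ndimage.correlate1d(volume, k, axis=ax, mode="constant", cval=0.0)
        return out
    # 26-connectivity: full 3x3x3 box minus the centre, separably
    k = np.array([1.0, 1.0, 1.0])
    out = volume.copy()
    for ax in range(3):
        out = ndimage.correlate1d(out, k, axis=ax, mode="constant", cval=0.0)
    return out - volume


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++-style centroid initialization on intensities."""
    centroids = [x[rng.integers(x.size)]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.asarray(centroids)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centroids.append(x[rng.integers(x.size)])
            continue
        centroids.append(x[np.searchsorted(np.cumsum(d2), rng.uniform(0, total))])
    return np.sort(np.asarray(centroids, dtype=float))


def _default_init(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Histogram-based initialization: multi-Otsu class means.

    Deterministic and robust to strongly unbalanced class sizes (a tiny
    hyperintense CSF compartment next to a large parenchyma class can
    derail a random init into merging CSF with blood).  Falls back to
    seeded k-means++ when the histogram is too degenerate to threshold.
    """
    try:
        thr = threshold_multiotsu(x, classes=k)
        bins = np.digitize(x, thr)
        means = [x[bins == i].mean() for i in range(k)]
        if np.any(np.isnan(means)):
            raise ValueError
        return np.sort(np.asarray(means, dtype=float))
    except ValueError:
        return _kmeanspp_init(x, k, np.random.default_rng(seed))


def fcm_mrf_segment(
    vol: MRVolume,
    cfg: SegmentationConfig,
    initial_centroids: np.ndarray | None = None,
) -> tuple[FuzzyMembership, LabelMap]:
    """Fuzzy c-means segmentation with MRF spatial regularization.

    Runs on the preprocessed volume's brain mask.  Deterministic given
    ``cfg.seed`` (centroid initialization is the only random step).
    The hard label map is the per-voxel argmax membership, with ties
    broken toward the brighter class; voxels outside the brain mask
    carry :data:`OUTSIDE_LABEL`.
    """
    if vol.mask is None:
        raise ValueError("volume has no brain mask; run preprocess first")
    mask = vol.mask
    x = vol.intensity[mask].astype(float)
    k = cfg.n_classes
    if np.unique(x).size < k:
        raise ValueError(f"fewer distinct intensities than classes (K={k})")

    if initial_centroids is None:
        v = _default_init(x, k, cfg.seed)
    else:
        v = np.sort(np.asarray(initial_centroids, dtype=float))
        if v.size != k:
            raise ValueError("initial_centroids must have n_classes entries")

    m = cfg.fuzzifier
    expo = 1.0 / (m - 1.0)
    eps = 1e-12
    n_nb = _neighbor_sum(mask.astype(float), cfg.neighborhood)[mask]

    u = None
    penalty = np.zeros((k, x.size))  # beta * s2 * mean neighborhood disagreement
    trace = []
    converged = False
    for it in range(cfg.max_iter):
        d2 = (x[None, :] - v[:, None]) ** 2
        w = (d2 + penalty + eps) ** (-expo)
        u = w / w.sum(axis=0, keepdims=True)

        um = u**m
        trace.append(float((um * (d2 + penalty)).sum()))

        v_new = (um * x[None, :]).sum(axis=1) / um.sum(axis=1)
        order = np.argsort(v_new)
        v_new = v_new[order]
        u = u[order]

        # refresh the neighborhood term from the current memberships;
        # s2 keeps the coupling commensurate with the data term
        if cfg.mrf_beta > 0:
            um = u**m
            d2s = (x[None, :] - v_new[:, None]) ** 2
            s2 = float((um * d2s).sum() / um.sum())
            for kk in range(k):
                grid = np.zeros(mask.shape)
                grid[mask] = u[kk]
                disagree = (n_nb - _neighbor_sum(grid, cfg.neighborhood)[mask]) / np.maximum(n_nb, 1.0)
                penalty[kk] = cfg.mrf_beta * s2 * disagree

        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        if shift < cfg.tol:
            converged = True
            break
    if not converged:
        msg = f"FCM did not converge in {cfg.max_iter} iterations (last shift {shift:.2e})"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)

    # memberships consistent with the final centroids
    d2 = (x[None, :] - v[:, None]) ** 2
    w = (d2 + penalty + eps) ** (-expo)
    u = w / w.sum(axis=0, keepdims=True)

    mem = np.zeros((k,) + mask.shape)
    for kk in range(k):
        mem[kk][mask] = u[kk]

    # argmax with ties toward the brighter class
    hard = (k - 1) - np.argmax(u[::-1], axis=0)
    labels = np.full(mask.shape, OUTSIDE_LABEL, dtype=np.uint8)
    labels[mask] = hard.astype(np.uint8)

    fuzzy = FuzzyMembership(
        membership=mem,
        centroids=v,
        mask=mask,
        config=cfg,
        objective_trace=np.asarray(trace),
        converged=converged,
    )
    return fuzzy, LabelMap(labels=labels, spacing=vol.spacing)


def select_csf_class(mem: FuzzyMembership) -> np.ndarray:
    """Candidate CSF mask: voxels whose argmax class is the brightest.

    Centroids are sorted ascending, so the brightest class has the last
    index; argmax ties are broken toward the brighter class.
    """
    k = mem.n_classes
    sub = mem.membership[:, mem.mask]
    hard = (k - 1) - np.argmax(sub[::-1], axis=0)
    out = np.zeros(mem.mask.shape, dtype=bool)
    out[mem.mask] = hard == (k - 1)
    return out


def apply_template(candidate: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Voxelwise AND of the candidate CSF mask with the prepared template."""
    candidate = np.asarray(candidate).astype(bool)
    template = np.asarray(template).astype(bool)
    if candidate.shape != template.shape:
        raise ValueError(
            f"shape mismatch: candidate {candidate.shape} vs template {template.shape}"
        )
    return candidate & template


def quantify_volume(mask: np.ndarray, spacing) -> CSFQuantification:
    """Voxel-counting volumetry: count x voxel volume, reported in ml."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    vox = voxel_volume_mm3(spacing)
    count = int(mask.sum())
    return CSFQuantification(
        voxel_count=count, voxel_volume_mm3=vox, volume_ml=count * vox / 1000.0
    )


@dataclass
class SegmentationPipelineResult:
    """All intermediates of the CSF extraction pipeline."""

    preprocessed: MRVolume
    membership: FuzzyMembership
    label_map: LabelMap
    candidate_mask: np.ndarray
    csf_mask: np.ndarray
    quantification: CSFQuantification


def segment_pipeline(
    vol: MRVolume,
    template: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> SegmentationPipelineResult:
    """Full CSF extraction: preprocess, segment, select, mask, quantify."""
    cfg = cfg or SegmentationConfig()
    pre = preprocess(vol)
    fuzzy, labels = fcm_mrf_segment(pre, cfg)
    candidate = select_csf_class(fuzzy)
    final = apply_template(candidate, template)
    quant = quantify_volume(final, vol.spacing)
    return SegmentationPipelineResult(
        preprocessed=pre,
        membership=fuzzy,
        label_map=labels,
        candidate_mask=candidate,
        csf_mask=final,
        quantification=quant,
    )
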