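"""Seed-based resting-state network mapping.

A seed region's mean time course is correlated with every brain voxel,
Pearson r is Fisher-z transformed (atanh, with r clipped at 1 - 1e-7 so z
stays finite), and maps are thresholded by a two-component Gaussian mixture
fit to the in-mask z values: the lower-mean component models the null bulk,
the higher-mean component the active voxels, and the threshold is the
smallest observed z above the null mean where the active component's
posterior exceeds one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .denoise import Volume4D

R_CLIP = 1.0 - 1e-7


@dataclass
class RSNMap:
    """Per-seed Fisher-z connectivity map."""

    zmap: np.ndarray
    seed_index: int
    threshold: float | None = None
    thresholded: np.ndarray | None = None

    @property
    def rmap(self) -> np.ndarray:
        return np.tanh(self.zmap)


@dataclass
class GmmThreshold:
    """Result of Gaussian-mixture thresholding of a z map."""

    threshold: float | None
    mask: np.ndarray
    degenerate: bool
    means: tuple[float, float] | None = None
    weights: tuple[float, float] | None = None


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping so perfect correlations stay finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def seed_correlation_map(
    volume: Volume4D, seed_mask: np.ndarray, brain_mask: np.ndarray,
    seed_index: int = 0,
) -> RSNMap:
    """Correlate the seed-mean time course with every brain voxel.

    Voxels with zero temporal variance get z = 0; voxels outside the brain
    mask are left at 0.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if np.any(seed_mask & ~brain_mask):
        raise ValueError("seed mask extends outside the brain mask")
    seed_ts = volume.mean_timeseries(seed_mask)
    seed_ts = seed_ts - seed_ts.mean()
    seed_sd = seed_ts.std()
    if seed_sd == 0:
        raise ValueError("seed mean time course has zero variance")
    y = volume.timeseries(brain_mask)  # T x V
    yc = y - y.mean(axis=0)
    sd = yc.std(axis=0)
    r = np.zeros(yc.shape[1])
    ok = sd > 0
    r[ok] = (seed_ts @ yc[:, ok]) / (y.shape[0] * seed_sd * sd[ok])
    zmap = np.zeros(volume.grid_shape)
    zmap[brain_mask] = fisher_z(r)
    return RSNMap(zmap=zmap, seed_index=seed_index)


def gmm_threshold(
    zmap: np.ndarray, brain_mask: np.ndarray, rng_seed: int = 0
) -> GmmThreshold:
    """Two-component Gaussian-mixture threshold of the in-mask z values.

    Initialization is deterministic: component means start at the 25th and
    95th percentiles with weights (0.9, 0.1), reflecting that suprathreshold
    voxels are an upper-tail minority.  Degenerate fits (near-constant data,
    or a component weight below 1e-3) fall back to "no suprathreshold
    voxels".
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    z = np.asarray(zmap, dtype=float)[brain_mask]
    if z.size < 100:
        raise ValueError(f"need at least 100 in-mask voxels, got {z.size}")
    empty = np.zeros_like(brain_mask)
    if z.std() < 1e-12:
        return GmmThreshold(None, empty, degenerate=True)

    q25, q95 = np.percentile(z, [25.0, 95.0])
    var0 = max(z.var() / 4.0, 1e-10)
    gmm = GaussianMixture(
        n_components=2,
        means_init=np.array([[q25], [q95]]),
        weights_init=np.array([0.9, 0.1]),
        precisions_init=np.array([[[1.0 / var0]], [[1.0 / var0]]]),
        random_state=rng_seed,
        n_init=1,
        max_iter=2000,
        tol=1e-6,
        reg_covar=1e-10 * max(z.var(), 1e-30),
    )
    gmm.fit(z[:, None])
    lo, hi = np.argsort(gmm.means_.ravel())
    means = (float(gmm.means_.ravel()[lo]), float(gmm.means_.ravel()[hi]))
    weights = (float(gmm.weights_[lo]), float(gmm.weights_[hi]))
    if min(weights) < 1e-3 or not np.isfinite(means).all():
        return GmmThreshold(None, empty, degenerate=True, means=means, weights=weights)

    candidates = np.sort(z[z > means[0]])
    if candidates.size == 0:
        return GmmThreshold(None, empty, degenerate=True, means=means, weights=weights)
    posterior = gmm.predict_proba(candidates[:, None])[:, hi]
    above = posterior > 0.5
    if not above.any():
        return GmmThreshold(None, empty, degenerate=True, means=means, weights=weights)
    threshold = float(candidates[np.argmax(above)])
    mask = (np.asarray(zmap) >= threshold) & brain_mask
    return GmmThreshold(threshold, mask, degenerate=False, means=means, weights=weights)


def threshold_map(rsn: RSNMap, brain_mask: np.ndarray, rng_seed: int = 0) -> RSNMap:
    """Attach the GMM threshold and binary mask to a map (in place)."""
    res = gmm_threshold(rsn.zmap, brain_mask, rng_seed)
    rsn.threshold = res.threshold
    rsn.thresholded = res.mask
    return rsn
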