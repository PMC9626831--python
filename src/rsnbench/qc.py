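"""Data-quality metrics for denoised resting-state maps.

Five metrics, computed per subject and technique (reproducibility is
cohort-level, per technique and seed):

* **Reproducibility** — split-half stability of the per-seed group-mean z
  maps, expressed as a pseudo-z against the permutation null built from the
  off-diagonal (seed-mismatched) spatial correlations.
* **Identifiability** — mean |z| inside the reference network mask divided
  by mean |z| outside it, on unthresholded maps.
* **Edge activity** — percentage of the brain-edge shell that survives
  Gaussian-mixture thresholding; a marker of residual motion artifact.
* **Spatial smoothness** — mean over six sphere radii of the ratio of
  low-frequency to high-frequency 3D Fourier amplitudes; Gaussian smoothing
  increases it, spatial fragmentation lowers it.
* **tDOF loss** — fraction of temporal degrees of freedom spent on
  censoring or component regressors (computed in :mod:`rsnbench.motion`).

Identifiability is refined by four sub-scores: mean connectivity (Fisher-z
averaged, reported as r) inside the target network (true positive), in gray
matter outside it (false positive), and in WM and CSF (physiological false
positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METRIC_COLUMNS = [
    "subject_id",
    "technique",
    "reproducibility_z",
    "identifiability_z",
    "edge_activity_pct",
    "smoothness",
    "tdof_fraction",
    "tp_conn_r",
    "fp_conn_r",
    "wm_conn_r",
    "csf_conn_r",
]


@dataclass
class MetricRecord:
    subject_id: str
    technique: str
    reproducibility_z: float
    identifiability_z: float
    edge_activity_pct: float
    smoothness: float
    tdof_fraction: float
    tp_conn_r: float
    fp_conn_r: float
    wm_conn_r: float
    csf_conn_r: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_activity_pct <= 100.0:
            raise ValueError("edge_activity_pct must lie in [0, 100]")
        if not 0.0 <= self.tdof_fraction <= 1.0:
            raise ValueError("tdof_fraction must lie in [0, 1]")


@dataclass
class ReproducibilityResult:
    """Per-seed pseudo-z plus the raw permutation distributions."""

    pseudo_z: np.ndarray  # S
    diagonal: np.ndarray  # S x P matched-seed correlations
    null: np.ndarray  # pooled off-diagonal correlations
    n_permutations: int
    null_mean: float = field(init=False)
    null_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_mean = float(self.null.mean())
        self.null_sd = float(self.null.std(ddof=1))


def _row_standardize(m: np.ndarray) -> np.ndarray:
    mc = m - m.mean(axis=1, keepdims=True)
    sd = mc.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return mc / sd


def split_half_reproducibility(
    maps: np.ndarray, n_permutations: int = 500, rng_seed: int = 0
) -> ReproducibilityResult:
    """Split-half reproducibility of per-seed group-mean maps.

    ``maps`` is (n_subjects, n_seeds, n_voxels), the unthresholded Fisher-z
    maps flattened over a common brain mask.  Each permutation splits the
    cohort in half (floor/ceil for odd sizes), averages each half's maps per
    seed, and computes the seed-by-seed matrix of spatial Pearson
    correlations between the halves.  Matched-seed (diagonal) values pool
    into one distribution per seed; mismatched-seed (off-diagonal) values
    pool into the null.  The per-seed pseudo-z is
    ``(mean(diag_s) - mean(null)) / sd(null)``.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("maps must be (n_subjects, n_seeds, n_voxels)")
    n, s, v = maps.shape
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    rng = np.random.default_rng(rng_seed)
    diag = np.empty((s, n_permutations))
    null_parts = []
    for p in range(n_permutations):
        order = rng.permutation(n)
        half1 = maps[order[: n // 2]].mean(axis=0)
        half2 = maps[order[n // 2 :]].mean(axis=0)
        c = _row_standardize(half1) @ _row_standardize(half2).T / v
        diag[:, p] = np.diag(c)
        off = c[~np.eye(s, dtype=bool)]
        null_parts.append(off)
    null = np.concatenate(null_parts)
    null_sd = null.std(ddof=1)
    if null_sd == 0:
        raise ValueError("degenerate null distribution (zero variance)")
    pseudo_z = (diag.mean(axis=1) - null.mean()) / null_sd
    return ReproducibilityResult(
        pseudo_z=pseudo_z, diagonal=diag, null=null, n_permutations=n_permutations
    )


def identifiability(
    zmap: np.ndarray, reference_mask: np.ndarray, brain_mask: np.ndarray
) -> float:
    """mean |z| inside the reference mask over mean |z| outside it."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    if np.any(reference_mask & ~brain_mask):
        raise ValueError("reference mask extends outside the brain mask")
    z = np.abs(np.asarray(zmap, dtype=float))
    inside = z[reference_mask].mean()
    outside = z[brain_mask & ~reference_mask].mean()
    if outside == 0:
        raise ValueError("degenerate map: zero mean |z| outside the reference mask")
    return float(inside / outside)


def connectivity_subscores(
    zmap: np.ndarray, atlas, reference_mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(tp_r, fp_r, wm_r, csf_r): region-mean connectivity, reported as r.

    Averages are taken on the Fisher-z scale (where correlations are
    additive) and back-transformed.  False positives are gray matter outside
    the target network; WM/CSF connectivity flags physiological leakage.
    """
    z = np.asarray(zmap, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    regions = {
        "target": reference_mask,
        "gm_outside": np.asarray(atlas.gm_mask, dtype=bool) & ~reference_mask,
        "wm": np.asarray(atlas.wm_mask, dtype=bool),
        "csf": np.asarray(atlas.csf_mask, dtype=bool),
    }
    out = []
    for name, mask in regions.items():
        if not mask.any():
            raise ValueError(f"region {name!r} is empty")
        out.append(float(np.tanh(z[mask].mean())))
    return tuple(out)  # type: ignore[return-value]


def edge_activity(
    active_mask: np.ndarray, edge_mask: np.ndarray, denominator: str = "edge"
) -> float:
    """Percentage of the edge shell that is suprathreshold.

    ``denominator="active"`` instead reports edge voxels as a share of all
    active voxels.
    """
    active = np.asarray(active_mask, dtype=bool)
    edge = np.asarray(edge_mask, dtype=bool)
    if active.shape != edge.shape:
        raise ValueError("mask shapes differ")
    if not edge.any():
        raise ValueError("edge mask is empty")
    hits = np.sum(active & edge)
    if denominator == "edge":
        return 100.0 * hits / edge.sum()
    if denominator == "active":
        return 100.0 * hits / active.sum() if active.any() else 0.0
    raise ValueError(f"unknown denominator {denominator!r}")


def spatial_smoothness(zmap: np.ndarray, n_radii: int = 6) -> float:
    """Fourier-ratio smoothness of a 3D map.

    The 3D DFT amplitude spectrum is split by spheres of radius
    ``j/(n_radii+1)`` of the maximum frequency radius (j = 1..n_radii, DC
    excluded); each radius contributes the ratio of the mean amplitude
    inside the sphere (low spatial frequencies) to the mean amplitude
    outside it (high frequencies).  The statistic is the mean of the ratios:
    spatially smooth, cohesive maps score high; fragmented, noisy maps score
    low.  Invariant to positive rescaling of the map.
    """
    z = np.asarray(zmap, dtype=float)
    if z.ndim != 3:
        raise ValueError("expected a 3D map")
    if min(z.shape) < 8:
        raise ValueError("every dimension must be >= 8 for 6 spectral shells")
    amp = np.abs(np.fft.fftn(z))
    freqs = [np.fft.fftfreq(nax) for nax in z.shape]
    # normalized frequency radius: each axis scaled by its Nyquist (0.5)
    grids = np.meshgrid(*[f / 0.5 for f in freqs], indexing="ij")
    radius = np.sqrt(sum(g**2 for g in grids))
    rmax = radius.max()
    dc = radius == 0.0
    ratios = []
    for j in range(1, n_radii + 1):
        rho = j / (n_radii + 1) * rmax
        inside = (radius <= rho) & ~dc
        outside = radius > rho
        if not inside.any() or not outside.any():
            raise ValueError("map too small for the requested shell radii")
        ratios.append(amp[inside].mean() / amp[outside].mean())
    return float(np.mean(ratios))


def collect_metrics(records: list[MetricRecord]) -> pd.DataFrame:
    """Long-format metrics table, one row per (subject, technique)."""
    if not records:
        raise ValueError("no metric records")
    df = pd.DataFrame([vars(r) for r in records], columns=METRIC_COLUMNS)
    cells = df.groupby(["subject_id", "technique"]).size()
    if (cells > 1).any():
        raise ValueError("duplicate (subject, technique) cells in metrics")
    return df.sort_values(["technique", "subject_id"]).reset_index(drop=True)


def check_complete(df: pd.DataFrame) -> None:
    """Raise listing any missing (subject, technique) cells."""
    subjects = df["subject_id"].unique()
    techniques = df["technique"].unique()
    have = set(zip(df["subject_id"], df["technique"]))
    missing = [
        (s, t) for s in subjects for t in techniques if (s, t) not in have
    ]
    if missing:
        raise ValueError(f"missing metric cells: {missing}")


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
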