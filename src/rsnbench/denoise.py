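"""Nuisance regression for 4D fMRI-like volumes.

Implements the building blocks of five noise-regression techniques commonly
compared in resting-state fMRI work:

1. ``censoring``           — 24 motion parameters, spike regressors for
                             high-motion frames (FWD >= cutoff), WM/CSF mean
                             signals and polynomial detrend removed in one
                             OLS regression, then a DFT bandpass.
                             (:func:`build_design_matrix` can alternatively
                             fold the bandpass into the design as
                             out-of-band frequency regressors.)
2. ``censoring_gs``        — technique 1 plus the global mean signal.
3. ``aggressive_aroma``    — spatial ICA on a heavily smoothed copy of the
                             data; the noise-labeled component time courses
                             are fully regressed out of the lightly smoothed
                             copy, followed by a DFT bandpass.
4. ``nonaggressive_aroma`` — as 3, but partial regression: the full mixing
                             matrix is fit jointly and only the noise
                             components' fitted contribution is subtracted
                             (fsl_regfilt semantics).
5. ``sock_style``          — noise-component time courses appended to the
                             technique-1 design (minus spike regressors) and
                             removed in one full regression.

Component *classification* is out of scope: noise labels are inputs, either
explicit or matched against known reference time courses
(:func:`label_noise_components`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .motion import (
    DEFAULT_HEAD_RADIUS_MM,
    CensorMask,
    MotionTrace,
    TdofReport,
    censor_mask,
    expand_motion_24,
    framewise_displacement,
    tdof_loss,
)

logger = logging.getLogger(__name__)

TECHNIQUES = (
    "censoring",
    "censoring_gs",
    "aggressive_aroma",
    "nonaggressive_aroma",
    "sock_style",
)

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume4D:
    """A 4D intensity array (X, Y, Z, T) with voxel geometry and timing."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def timeseries(self, mask: np.ndarray) -> np.ndarray:
        """(T, V) matrix of the voxel series inside a boolean mask."""
        return self.data[np.asarray(mask, dtype=bool)].T

    def mean_timeseries(self, mask: np.ndarray) -> np.ndarray:
        return self.timeseries(mask).mean(axis=1)

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=data)


@dataclass
class DesignMatrix:
    """Labeled T x K confound matrix with per-column category tags."""

    values: np.ndarray
    labels: list[str]
    categories: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design values must be 2-D")
        if not (len(self.labels) == len(self.categories) == self.values.shape[1]):
            raise ValueError("labels/categories length must equal column count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def count(self, category: str) -> int:
        return sum(c == category for c in self.categories)

    def append(self, values: np.ndarray, labels: list[str], category: str) -> "DesignMatrix":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] != self.n_timepoints:
            values = values.T
        return DesignMatrix(
            values=np.hstack([self.values, values]),
            labels=self.labels + list(labels),
            categories=self.categories + [category] * values.shape[1],
        )


@dataclass
class Decomposition:
    """Spatial-ICA result: mixing time courses, spatial maps, noise flags.

    ``mixing`` is T x C with variance-normalized columns; ``maps`` is C x V
    over the voxels of the mask the decomposition was computed on.  The
    noise labels start all-False — classification is an external input.
    """

    mixing: np.ndarray
    maps: np.ndarray
    noise_label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.mixing.shape[1] != self.maps.shape[0]:
            raise ValueError("mixing and maps disagree on component count")
        if self.mixing.shape[1] >= self.mixing.shape[0]:
            raise ValueError("need fewer components than timepoints")
        if self.noise_label is None:
            self.noise_label = np.zeros(self.n_components, dtype=bool)
        self.noise_label = np.asarray(self.noise_label, dtype=bool)
        if self.noise_label.shape[0] != self.n_components:
            raise ValueError("noise_label length must equal component count")

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    @property
    def n_noise(self) -> int:
        return int(self.noise_label.sum())


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------


def drift_regressors(n_timepoints: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns P_0..P_order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_timepoints)
    return legendre.legvander(x, order)


def frequency_regressors(
    n_timepoints: int, tr: float, low_hz: float, high_hz: float
) -> tuple[np.ndarray, list[str]]:
    """Sine/cosine pairs at every DFT frequency OUTSIDE [low_hz, high_hz].

    Regressing these columns out implements a bandpass filter inside the
    same OLS step as the other confounds (3dDeconvolve-style simultaneous
    bandpass), so censored frames never corrupt the filter.  DC (k=0) is
    left to the drift block; at the Nyquist bin only the cosine is non-zero.
    """
    t = np.arange(n_timepoints)
    cols, labels = [], []
    for k in range(1, n_timepoints // 2 + 1):
        f = k / (n_timepoints * tr)
        if low_hz <= f <= high_hz:
            continue
        phase = 2.0 * np.pi * k * t / n_timepoints
        cols.append(np.cos(phase))
        labels.append(f"cos_f{f:.6f}")
        if 2 * k != n_timepoints:  # sine vanishes identically at Nyquist
            cols.append(np.sin(phase))
            labels.append(f"sin_f{f:.6f}")
    if not cols:
        return np.empty((n_timepoints, 0)), []
    return np.column_stack(cols), labels


def build_design_matrix(
    trace: MotionTrace,
    wm_ts: np.ndarray,
    csf_ts: np.ndarray,
    *,
    global_ts: np.ndarray | None = None,
    censor: CensorMask | None = None,
    detrend_order: int = 3,
    passband: tuple[float, float] | None = (0.009, 0.08),
    tr: float | None = None,
    n_timepoints: int | None = None,
) -> DesignMatrix:
    """Assemble the full confound design for the censoring-style techniques.

    Columns (in order): 24 motion parameters, one spike indicator per
    censored frame, WM and CSF mean signals, the global signal when given,
    Legendre drift up to ``detrend_order``, and out-of-band frequency
    regressors when ``passband`` is given.
    """
    tr = trace.tr if tr is None else tr
    T = trace.n_timepoints if n_timepoints is None else n_timepoints
    if trace.n_timepoints != T:
        raise ValueError("motion trace length does not match n_timepoints")
    for name, series in (("wm_ts", wm_ts), ("csf_ts", csf_ts), ("global_ts", global_ts)):
        if series is not None and np.asarray(series).shape[0] != T:
            raise ValueError(f"{name} length does not match n_timepoints")

    mp = expand_motion_24(trace)
    labels = [f"mp{i + 1}" for i in range(24)]
    categories = ["motion"] * 24
    blocks = [mp]

    if censor is not None:
        if censor.keep.shape[0] != T:
            raise ValueError("censor mask length does not match n_timepoints")
        for idx in censor.dropped_indices:
            spike = np.zeros(T)
            spike[idx] = 1.0
            blocks.append(spike[:, None])
            labels.append(f"spike_t{idx}")
            categories.append("spike")

    blocks.append(np.asarray(wm_ts, dtype=float)[:, None])
    labels.append("wm")
    categories.append("tissue")
    blocks.append(np.asarray(csf_ts, dtype=float)[:, None])
    labels.append("csf")
    categories.append("tissue")
    if global_ts is not None:
        blocks.append(np.asarray(global_ts, dtype=float)[:, None])
        labels.append("global")
        categories.append("global")

    blocks.append(drift_regressors(T, detrend_order))
    labels += [f"drift_p{p}" for p in range(detrend_order + 1)]
    categories += ["drift"] * (detrend_order + 1)

    if passband is not None:
        low, high = passband
        if not 0 < low < high < 0.5 / tr:
            raise ValueError("passband must satisfy 0 < low < high < Nyquist")
        freq, freq_labels = frequency_regressors(T, tr, low, high)
        blocks.append(freq)
        labels += freq_labels
        categories += ["frequency"] * freq.shape[1]

    values = np.hstack(blocks)
    if values.shape[1] >= T:
        raise ValueError(
            f"design has {values.shape[1]} columns for only {T} timepoints; "
            "the OLS fit is over-determined"
        )
    return DesignMatrix(values=values, labels=labels, categories=categories)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def _centered_design(design: DesignMatrix) -> np.ndarray:
    """Center columns and drop those that are (near) zero after centering."""
    x = design.values - design.values.mean(axis=0)
    scale = np.abs(design.values).max(axis=0)
    keep = np.abs(x).max(axis=0) > 1e-12 * np.maximum(scale, 1.0)
    if not np.all(keep):
        dropped = [lbl for lbl, k in zip(design.labels, keep) if not k]
        logger.warning("dropping constant design columns: %s", dropped)
    return x[:, keep]


def _ols_residual(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual of Y (T x V) on centered X, with the Y column means restored.

    Uses a minimum-norm least-squares solve so rank-deficient designs are
    handled; residuals are orthogonal to the column span either way.
    """
    mean = y.mean(axis=0)
    yc = y - mean
    if x.shape[1] == 0:
        return y.copy()
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    return yc - x @ beta + mean


def regress_full(volume: Volume4D, design: DesignMatrix) -> Volume4D:
    """OLS-remove every design column from every voxel series (aggressive).

    The design is mean-centered, the fit removes all variance in its span,
    and the voxel mean is restored afterwards.
    """
    if design.n_timepoints != volume.n_timepoints:
        raise ValueError("design and volume disagree on n_timepoints")
    if design.n_columns >= volume.n_timepoints:
        raise ValueError("design has too many columns for OLS")
    x = _centered_design(design)
    shape = volume.data.shape
    y = volume.data.reshape(-1, shape[3]).T  # T x V
    resid = _ols_residual(y, x)
    return volume.with_data(resid.T.reshape(shape))


def regress_components_aggressive(
    volume: Volume4D,
    decomposition: Decomposition,
    extra_design: DesignMatrix | None = None,
) -> Volume4D:
    """Fully regress the noise-labeled component time courses out.

    Removes *all* variance the noise time courses (plus any extra confound
    columns) explain in each voxel.
    """
    if decomposition.n_noise == 0:
        raise ValueError("no components are labeled as noise")
    if decomposition.mixing.shape[0] != volume.n_timepoints:
        raise ValueError("decomposition and volume disagree on n_timepoints")
    cols = decomposition.mixing[:, decomposition.noise_label]
    labels = [f"ic{i}" for i in np.flatnonzero(decomposition.noise_label)]
    design = DesignMatrix(cols, labels, ["component"] * cols.shape[1])
    if extra_design is not None:
        design = design.append(extra_design.values, extra_design.labels, "component")
        design.categories[cols.shape[1]:] = extra_design.categories
    return regress_full(volume, design)


def regress_components_nonaggressive(
    volume: Volume4D, decomposition: Decomposition
) -> Volume4D:
    """Partial (fsl_regfilt-style) removal of noise components.

    The FULL mixing matrix is fit to each voxel jointly; only the noise
    components' fitted contribution is subtracted, so variance a noise
    component shares with a retained component survives.
    """
    if decomposition.n_noise == 0:
        raise ValueError("no components are labeled as noise")
    m = decomposition.mixing
    if m.shape[0] != volume.n_timepoints:
        raise ValueError("decomposition and volume disagree on n_timepoints")
    mc = m - m.mean(axis=0)
    cond = np.linalg.cond(mc)
    if cond > 1e8:
        logger.warning("mixing matrix ill-conditioned (cond=%.3g); using pinv", cond)
    shape = volume.data.shape
    y = volume.data.reshape(-1, shape[3]).T
    mean = y.mean(axis=0)
    beta = np.linalg.pinv(mc) @ (y - mean)
    clean = y - mc[:, decomposition.noise_label] @ beta[decomposition.noise_label]
    return volume.with_data(clean.T.reshape(shape))


# ---------------------------------------------------------------------------
# Filtering, smoothing, ICA
# ---------------------------------------------------------------------------


def bandpass_filter(data, low_hz: float, high_hz: float, tr: float):
    """Hard DFT bandpass along the time axis; DC is outside every band.

    Accepts a :class:`Volume4D` or an array whose last axis is time, and
    returns the same type/shape.
    """
    if isinstance(data, Volume4D):
        return data.with_data(bandpass_filter(data.data, low_hz, high_hz, data.tr))
    arr = np.asarray(data, dtype=float)
    n = arr.shape[-1]
    if not 0 < low_hz < high_hz < 0.5 / tr + 1e-12:
        raise ValueError("need 0 < low < high <= Nyquist")
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not np.any(keep):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz contains no DFT bin at T={n}, tr={tr}"
        )
    spec = np.fft.rfft(arr, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def smooth_volume(volume: Volume4D, fwhm_mm: float) -> Volume4D:
    """Gaussian spatial smoothing, kernel given as FWHM in mm."""
    sigma_vox = [
        fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / vs for vs in volume.voxel_size
    ]
    out = ndimage.gaussian_filter(volume.data, sigma=(*sigma_vox, 0.0))
    return volume.with_data(out)


def default_n_components(volume: Volume4D, brain_mask: np.ndarray,
                         explained_variance: float = 0.95) -> int:
    """Component count that retains ``explained_variance`` of the PCA spectrum."""
    x = volume.timeseries(brain_mask).T  # V x T
    pca = PCA(n_components=min(x.shape) - 1, svd_solver="full")
    pca.fit(x)
    c = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_),
                            explained_variance) + 1)
    return max(2, min(c, volume.n_timepoints - 1))


def decompose_spatial_ica(
    volume: Volume4D,
    brain_mask: np.ndarray,
    n_components: int | None = None,
    rng_seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> Decomposition:
    """Spatial ICA of the in-mask data.

    The data matrix (voxels x timepoints) is unmixed into spatially
    independent maps; ``mixing`` holds the associated component time
    courses.  Deterministic for a fixed ``rng_seed``; noise labels are left
    all-False (classification is an external input).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    if n_components is None:
        n_components = default_n_components(volume, brain_mask)
    if n_components >= volume.n_timepoints:
        raise ValueError("n_components must be smaller than n_timepoints")
    x = volume.timeseries(brain_mask).T  # V x T (samples x features)
    # FastICA can stall from an unlucky initial rotation, and on noisy data
    # the tightest tolerance may never be reached (near-Gaussian residual
    # directions cycle); retry deterministic re-initializations at
    # progressively looser tolerances before giving up
    sources = ica = None
    attempts = [tol, tol, 10 * tol, 10 * tol, 100 * tol, 100 * tol, 100 * tol]
    for attempt, attempt_tol in enumerate(attempts):
        candidate = FastICA(
            n_components=n_components,
            random_state=rng_seed + 9973 * attempt,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=attempt_tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = candidate.fit_transform(x)  # V x C
                ica = candidate
                break
            except ConvergenceWarning:
                continue
    if ica is None:
        raise RuntimeError(
            f"spatial ICA did not converge within {max_iter} iterations "
            f"in any of {len(attempts)} initializations"
        )
    mixing = ica.mixing_  # T x C
    maps = sources.T  # C x V
    scale = mixing.std(axis=0)
    scale[scale == 0] = 1.0
    return Decomposition(mixing=mixing / scale, maps=maps * scale[:, None])


def label_noise_components(
    decomposition: Decomposition,
    noise_timecourses: np.ndarray,
    signal_timecourses: np.ndarray | None = None,
    min_abs_r: float = 0.4,
    ensure_at_least_one: bool = False,
) -> np.ndarray:
    """Label components by temporal match against reference time courses.

    A component is flagged as noise when its best absolute Pearson
    correlation with any reference noise time course reaches ``min_abs_r``
    and (when signal references are given) beats its best match with any
    signal time course.  With ``ensure_at_least_one``, the single
    best-matching component is flagged even below threshold (practical
    classifiers essentially always find some motion component).  Returns
    the boolean labels and stores them on the decomposition.
    """

    def best_abs_r(tc: np.ndarray, refs: np.ndarray) -> float:
        r = [abs(np.corrcoef(tc, refs[:, q])[0, 1]) for q in range(refs.shape[1])]
        return max(r) if r else 0.0

    noise_timecourses = np.asarray(noise_timecourses, dtype=float)
    n = decomposition.n_components
    r_noise = np.empty(n)
    labels = np.zeros(n, dtype=bool)
    for c in range(n):
        tc = decomposition.mixing[:, c]
        r_noise[c] = best_abs_r(tc, noise_timecourses)
        r_signal = (
            best_abs_r(tc, np.asarray(signal_timecourses, dtype=float))
            if signal_timecourses is not None
            else 0.0
        )
        labels[c] = r_noise[c] >= min_abs_r and r_noise[c] > r_signal
    if ensure_at_least_one and not labels.any():
        labels[int(np.argmax(r_noise))] = True
    decomposition.noise_label = labels
    return labels


# ---------------------------------------------------------------------------
# Technique orchestration
# ---------------------------------------------------------------------------


@dataclass
class TechniqueOptions:
    """Tunable knobs of :func:`apply_technique`.

    ``ica_fwhm_mm``/``data_fwhm_mm`` implement the two-kernel workflow
    (ICA on a 6 mm-smoothed copy, regression on a 4 mm-smoothed copy); set
    them to None to disable smoothing on tiny grids.  Noise labels for the
    component-based techniques come either from ``noise_labels`` directly or
    from matching against ``noise_timecourses`` (ground truth in synthetic
    runs, or user-supplied).
    """

    fwd_cutoff_mm: float = 0.5
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    detrend_order: int = 3
    band: tuple[float, float] = (0.009, 0.08)
    ica_fwhm_mm: float | None = 6.0
    data_fwhm_mm: float | None = 4.0
    n_components: int | None = None
    rng_seed: int = 0
    noise_labels: np.ndarray | None = None
    noise_timecourses: np.ndarray | None = None
    signal_timecourses: np.ndarray | None = None
    label_min_abs_r: float = 0.4
    label_ensure_at_least_one: bool = True
    regress_tissue_after_components: bool = False


def read_noise_label_file(path, n_components: int) -> np.ndarray:
    """Read a noise-label file: one 1-based component index per line."""
    idx = np.loadtxt(path, dtype=int, ndmin=1)
    if np.any(idx < 1) or np.any(idx > n_components):
        raise ValueError(f"{path}: component indices must be in 1..{n_components}")
    labels = np.zeros(n_components, dtype=bool)
    labels[idx - 1] = True
    return labels


def _resolve_labels(
    decomposition: Decomposition, opts: TechniqueOptions
) -> np.ndarray:
    if opts.noise_labels is not None:
        labels = np.asarray(opts.noise_labels, dtype=bool)
        if labels.shape[0] != decomposition.n_components:
            raise ValueError("noise_labels length does not match component count")
        decomposition.noise_label = labels
        return labels
    if opts.noise_timecourses is None:
        raise ValueError(
            "component-based techniques need noise_labels or noise_timecourses"
        )
    return label_noise_components(
        decomposition,
        opts.noise_timecourses,
        opts.signal_timecourses,
        opts.label_min_abs_r,
        ensure_at_least_one=opts.label_ensure_at_least_one,
    )


def apply_technique(
    subject,
    technique: str,
    atlas,
    options: TechniqueOptions | None = None,
) -> tuple[Volume4D, TdofReport]:
    """Run one of the five denoising techniques on a subject.

    ``subject`` must expose ``volume`` (:class:`Volume4D`) and ``motion``
    (:class:`MotionTrace`); ``atlas`` must expose ``brain_mask``,
    ``wm_mask`` and ``csf_mask``.  Returns the cleaned volume (same length
    as the input — censored frames are spike-regressed, not deleted) and
    the temporal-degrees-of-freedom report.
    """
    opts = options or TechniqueOptions()
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")

    volume: Volume4D = subject.volume
    trace: MotionTrace = subject.motion
    T = volume.n_timepoints

    data_vol = (
        smooth_volume(volume, opts.data_fwhm_mm)
        if opts.data_fwhm_mm
        else volume
    )
    wm_ts = data_vol.mean_timeseries(atlas.wm_mask)
    csf_ts = data_vol.mean_timeseries(atlas.csf_mask)

    if technique in ("censoring", "censoring_gs"):
        fwd = framewise_displacement(trace, opts.head_radius_mm)
        mask = censor_mask(fwd, opts.fwd_cutoff_mm)
        design = build_design_matrix(
            trace,
            wm_ts,
            csf_ts,
            global_ts=(
                data_vol.mean_timeseries(atlas.brain_mask)
                if technique == "censoring_gs"
                else None
            ),
            censor=mask,
            detrend_order=opts.detrend_order,
            passband=None,
        )
        cleaned = regress_full(data_vol, design)
        cleaned = bandpass_filter(cleaned, opts.band[0], opts.band[1], cleaned.tr)
        report = tdof_loss(T, censor=mask)
        return cleaned, report

    if opts.noise_labels is None and opts.noise_timecourses is None:
        raise ValueError(
            "component-based techniques need noise_labels or noise_timecourses"
        )
    ica_vol = (
        smooth_volume(volume, opts.ica_fwhm_mm) if opts.ica_fwhm_mm else volume
    )
    decomposition = decompose_spatial_ica(
        ica_vol, atlas.brain_mask, opts.n_components, opts.rng_seed
    )
    labels = _resolve_labels(decomposition, opts)
    if not labels.any():
        raise ValueError(f"technique {technique!r}: no component labeled as noise")

    if technique == "sock_style":
        design = build_design_matrix(
            trace,
            wm_ts,
            csf_ts,
            censor=None,
            detrend_order=opts.detrend_order,
            passband=None,
        )
        noise_tcs = decomposition.mixing[:, labels]
        design = design.append(
            noise_tcs, [f"ic{i}" for i in np.flatnonzero(labels)], "component"
        )
        cleaned = regress_full(data_vol, design)
        cleaned = bandpass_filter(cleaned, opts.band[0], opts.band[1], cleaned.tr)
        return cleaned, tdof_loss(T, noise_labels=labels)

    extra = None
    if opts.regress_tissue_after_components:
        extra = DesignMatrix(
            np.column_stack([wm_ts, csf_ts]), ["wm", "csf"], ["tissue", "tissue"]
        )
    if technique == "aggressive_aroma":
        cleaned = regress_components_aggressive(data_vol, decomposition, extra)
    else:  # nonaggressive_aroma
        cleaned = regress_components_nonaggressive(data_vol, decomposition)
    cleaned = bandpass_filter(cleaned, opts.band[0], opts.band[1], cleaned.tr)
    return cleaned, tdof_loss(T, noise_labels=labels)
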