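"""Head-motion bookkeeping: framewise displacement, censoring, confound expansion.

Rigid-body motion is described by six parameters per frame: three rotations
(radians) and three translations (mm).  Framewise displacement (FWD) collapses
the frame-to-frame change of all six into a single scalar in mm by
linearizing rotations on a sphere of nominal head radius (default 50 mm):

    FWD[t] = |Δtx| + |Δty| + |Δtz| + r · (|Δrx| + |Δry| + |Δrz|)

with FWD[0] defined as 0 (no preceding frame).  FWD thresholds of 0.2 mm and
0.5 mm are the conventional censoring cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_HEAD_RADIUS_MM = 50.0

#: Column order of a 6-parameter motion file (rotations in radians, then
#: translations in mm), one row per frame.
PARAM_COLUMNS = ("rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z")


@dataclass
class MotionTrace:
    """Per-frame rigid-body trajectory.

    Parameters
    ----------
    params : (T, 6) array
        Columns ``rot_x, rot_y, rot_z`` in radians and
        ``trans_x, trans_y, trans_z`` in mm.
    tr : float
        Repetition time in seconds.
    """

    params: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion params must be T x 6, got {self.params.shape}")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace needs at least one frame")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class CensorMask:
    """Boolean keep/drop decision per frame at a given FWD cutoff."""

    keep: np.ndarray
    cutoff_mm: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.cutoff_mm <= 0:
            raise ValueError("cutoff_mm must be positive")

    @property
    def n_dropped(self) -> int:
        return int(np.sum(~self.keep))

    @property
    def dropped_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.keep)


@dataclass
class TdofReport:
    """Temporal-degrees-of-freedom loss for one subject and technique.

    Each censored frame, and each noise component used as a regressor,
    removes one temporal degree of freedom from the series.
    """

    n_timepoints: int
    n_lost: int
    source: str  # "censoring" | "components" | "regressors"
    fraction_lost: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_lost <= self.n_timepoints:
            raise ValueError(
                f"n_lost={self.n_lost} outside [0, {self.n_timepoints}]"
            )
        self.fraction_lost = self.n_lost / self.n_timepoints


def framewise_displacement(
    trace: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement series in mm; first frame is 0 by convention."""
    d = np.diff(trace.params, axis=0)
    fwd = np.zeros(trace.n_timepoints)
    fwd[1:] = np.sum(np.abs(d[:, 3:]), axis=1) + head_radius_mm * np.sum(
        np.abs(d[:, :3]), axis=1
    )
    return fwd


def censor_mask(fwd: np.ndarray, cutoff_mm: float) -> CensorMask:
    """Mark frames with FWD at or above ``cutoff_mm`` for censoring."""
    fwd = np.asarray(fwd, dtype=float)
    if fwd.size == 0:
        raise ValueError("empty FWD series")
    if cutoff_mm <= 0:
        raise ValueError("cutoff_mm must be positive")
    return CensorMask(keep=fwd < cutoff_mm, cutoff_mm=cutoff_mm)


def expand_motion_24(trace: MotionTrace) -> np.ndarray:
    """Friston-style 24-parameter expansion ``[R, R_lag1, R^2, R_lag1^2]``.

    Column blocks of 6, in the order: the parameters, their one-frame
    backward lag (first row zero-filled), their squares, and the squared
    lags.
    """
    if trace.n_timepoints < 2:
        raise ValueError("24-parameter expansion needs at least 2 frames")
    r = trace.params
    lag = np.zeros_like(r)
    lag[1:] = r[:-1]
    return np.hstack([r, lag, r**2, lag**2])


def tdof_loss(
    n_timepoints: int,
    *,
    censor: CensorMask | None = None,
    noise_labels: np.ndarray | None = None,
) -> TdofReport:
    """Account for temporal degrees of freedom lost to a cleanup step.

    Exactly one of ``censor`` (frames dropped) or ``noise_labels`` (boolean
    per-component flags; each noise component costs one frame of freedom)
    must be given.
    """
    if (censor is None) == (noise_labels is None):
        raise ValueError("pass exactly one of censor= or noise_labels=")
    if censor is not None:
        if censor.keep.shape[0] != n_timepoints:
            raise ValueError("censor mask length does not match n_timepoints")
        return TdofReport(n_timepoints, censor.n_dropped, source="censoring")
    labels = np.asarray(noise_labels, dtype=bool)
    if labels.ndim != 1:
        raise ValueError("noise_labels must be a 1-D boolean vector")
    return TdofReport(n_timepoints, int(labels.sum()), source="components")


def load_motion_file(path, tr: float, *, degrees: bool = False) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion file.

    Column order is rot_x rot_y rot_z trans_x trans_y trans_z with rotations
    in radians; pass ``degrees=True`` for dialects that store rotations in
    degrees (converted on load).
    """
    params = np.loadtxt(path, ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {params.shape[1]}")
    if degrees:
        params = params.copy()
        params[:, :3] = np.deg2rad(params[:, :3])
    return MotionTrace(params=params, tr=tr)


def save_motion_file(path, trace: MotionTrace) -> None:
    np.savetxt(path, trace.params, fmt="%.8f")
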