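"""Synthetic rs-fMRI cohorts with known ground truth.

Real resting-state acquisitions of older adults mix low-frequency (<0.1 Hz)
network fluctuations with tremor-like high-frequency head motion,
edge-concentrated motion artifacts, shared physiological signals in
WM/CSF/global compartments, slow scanner drift, and thermal noise.  This
module builds digital phantoms with exactly those ingredients — and returns
the planted time courses and labels — so every downstream stage (denoising,
connectivity mapping, quality metrics, ranking) can be tested end to end
without any acquisition.

Geometry defaults mirror a typical clinical protocol: 2.5 s TR, 12-minute
runs (288 frames), 64 x 64 in-plane matrix.  Test- and desk-scale runs use
smaller grids; nothing in the construction depends on absolute size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .denoise import Volume4D
from .motion import MotionTrace, framewise_displacement, save_motion_file

logger = logging.getLogger(__name__)

#: Calibrated so tremor-like traces show many FWD spikes above 0.2 mm but
#: only a few above 0.5 mm (FWD approximately N(0.31, 0.12) mm at these
#: values, on a 50 mm head sphere).
HF_TRANS_JITTER_MM = 0.08
HF_ROT_JITTER_RAD = 0.0002
SMOOTH_STEP_MM = 0.01
SMOOTH_STEP_RAD = 2e-5

EDGE_DECAY_SCALE_VOX = 2.0  # e-folding of the motion-artifact weight from the brain edge
EDGE_SHELL_VOX = 2          # edge mask = brain minus its 2-voxel erosion
PHYSIO_COMMON_COUPLING = 0.6  # share of the global physio core in WM/CSF signals


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PhantomAtlas:
    """Mask collection of a digital head phantom.

    Concentric compartments: a CSF core, a WM shell, a GM shell carrying the
    networks, and a 2-voxel edge shell at the brain boundary.  Each seed is
    a small blob inside one reference network.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    edge_mask: np.ndarray
    seed_masks: list[np.ndarray]
    reference_networks: list[np.ndarray]
    seed_to_network: dict[int, int]

    @property
    def n_seeds(self) -> int:
        return len(self.seed_masks)

    @property
    def n_networks(self) -> int:
        return len(self.reference_networks)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        for name in ("gm_mask", "wm_mask", "csf_mask", "edge_mask"):
            m = getattr(self, name)
            if m.shape != tuple(self.grid_shape):
                raise ValueError(f"{name} shape mismatch")
            if np.any(m & ~self.brain_mask):
                raise ValueError(f"{name} not contained in brain_mask")
        if np.any(self.wm_mask & self.gm_mask):
            raise ValueError("WM and GM overlap")
        if np.any(self.csf_mask & self.gm_mask):
            raise ValueError("CSF and GM overlap")
        if np.any(self.edge_mask & self.gm_mask):
            raise ValueError("edge shell and GM overlap")
        for i, seed in enumerate(self.seed_masks):
            if not seed.any():
                raise ValueError(f"seed {i} is empty")
            net = self.seed_to_network.get(i)
            if net is not None and np.any(seed & ~self.reference_networks[net]):
                raise ValueError(f"seed {i} leaves its network {net}")


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator (amplitudes in baseline-image units).

    The defaults describe an older-adult-like acquisition: 1% network
    fluctuations over a baseline of 100, motion artifacts that dominate at
    the brain edge, moderate shared physiological signal, unit thermal
    noise, and half the cohort showing tremor-like high-frequency motion.

    Three coupling knobs plant the shared-variance structure of real
    recordings: ``shared_variance`` couples the physiological (WM/CSF/
    global) signals to the network time courses (vascular confounding of
    connectivity); ``artifact_network_coupling`` couples the motion
    artifact to the networks; ``artifact_physio_coupling`` couples the
    motion artifact to the global physiological signal (breathing drives
    both head motion and global BOLD fluctuations).  These couplings are
    what makes partial (non-aggressive) component regression leak noise
    while full (aggressive) regression removes it.
    """

    n_subjects: int = 12
    n_timepoints: int = 288
    tr: float = 2.5
    baseline: float = 100.0
    network_amplitude: float = 1.0
    motion_artifact_amplitude: float = 2.5
    physio_amplitude: float = 0.7
    drift_amplitude: float = 1.0
    thermal_sd: float = 1.0
    hf_motion_fraction: float = 0.5
    shared_variance: float = 0.5
    artifact_network_coupling: float = 0.15
    artifact_physio_coupling: float = 0.45
    passband: tuple[float, float] = (0.01, 0.08)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline",
            "network_amplitude",
            "motion_artifact_amplitude",
            "physio_amplitude",
            "drift_amplitude",
            "thermal_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        low, high = self.passband
        if not 0 < low < high < 0.5 / self.tr:
            raise ValueError("passband must satisfy 0 < low < high < Nyquist")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if not 0 <= self.shared_variance < 1:
            raise ValueError("shared_variance must lie in [0, 1)")
        ka, rho = self.artifact_network_coupling, self.artifact_physio_coupling
        if ka < 0 or rho < 0 or ka**2 + rho**2 >= 1:
            raise ValueError(
                "artifact couplings must be non-negative with "
                "artifact_network_coupling^2 + artifact_physio_coupling^2 < 1"
            )
        if not 0 <= self.hf_motion_fraction <= 1:
            raise ValueError("hf_motion_fraction must lie in [0, 1]")


@dataclass
class SyntheticSubject:
    """One simulated acquisition plus its ground truth."""

    subject_id: str
    volume: Volume4D
    motion: MotionTrace
    motion_mode: str
    truth_network_timecourses: np.ndarray  # T x M
    truth_noise_timecourses: np.ndarray  # T x Q (motion artifact + physio)
    n_artifact_timecourses: int = 6
    truth_component_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T = self.volume.n_timepoints
        if self.truth_network_timecourses.shape[0] != T:
            raise ValueError("network time courses do not match volume length")
        if self.truth_noise_timecourses.shape[0] != T:
            raise ValueError("noise time courses do not match volume length")
        if self.truth_component_labels is None:
            m = self.truth_network_timecourses.shape[1]
            q = self.truth_noise_timecourses.shape[1]
            self.truth_component_labels = np.r_[
                np.zeros(m, dtype=bool), np.ones(q, dtype=bool)
            ]

    @property
    def truth_artifact_timecourses(self) -> np.ndarray:
        """Motion-artifact time courses only — what a motion-targeted
        component classifier is meant to find."""
        return self.truth_noise_timecourses[:, : self.n_artifact_timecourses]


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------


def _radial(grid_shape, semi_axes) -> np.ndarray:
    """Normalized ellipsoidal radius around the grid center."""
    coords = np.meshgrid(
        *[np.arange(n) - (n - 1) / 2.0 for n in grid_shape], indexing="ij"
    )
    return np.sqrt(sum((c / a) ** 2 for c, a in zip(coords, semi_axes)))


def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform unit vectors on the sphere, randomly rotated."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # random rotation so different seeds give different layouts
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return pts @ q.T


def make_phantom_atlas(
    grid_shape=(32, 32, 32),
    n_seeds: int = 22,
    n_networks: int = 14,
    rng_seed: int = 0,
    voxel_size=(3.4, 3.4, 3.4),
) -> PhantomAtlas:
    """Build a phantom atlas with ``n_networks`` GM blobs and ``n_seeds`` seeds.

    Network centers sit on a Fibonacci lattice over the mid-GM sphere so
    they are evenly spread and deterministic for a fixed ``rng_seed``.
    Raises when the grid cannot hold the requested number of disjoint
    networks.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if min(grid_shape) < 16:
        raise ValueError("grid too small: every dimension must be >= 16 voxels")
    rng = np.random.default_rng(rng_seed)
    shape_arr = np.asarray(grid_shape, dtype=float)
    center = (shape_arr - 1.0) / 2.0

    brain = _radial(grid_shape, 0.42 * shape_arr) <= 1.0
    interior = ndimage.binary_erosion(brain, iterations=EDGE_SHELL_VOX)
    edge = brain & ~interior
    csf = _radial(grid_shape, 0.10 * shape_arr) <= 1.0
    wm_ball = _radial(grid_shape, 0.22 * shape_arr) <= 1.0
    wm = wm_ball & ~csf & interior
    gm = interior & ~wm_ball

    r_net = max(1.8, 0.09 * min(grid_shape))
    dirs = _fibonacci_directions(n_networks, rng)
    centers = center + dirs * (0.32 * shape_arr)
    if n_networks > 1:
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        min_d = d[np.triu_indices(n_networks, 1)].min()
        if min_d < 2.0 * r_net + 1.0:
            raise ValueError(
                f"cannot pack {n_networks} networks of radius {r_net:.1f} vox "
                f"on grid {grid_shape} (closest centers {min_d:.1f} vox apart)"
            )

    idx = np.indices(grid_shape).reshape(3, -1).T
    networks: list[np.ndarray] = []
    for c in centers:
        ball = (np.linalg.norm(idx - c, axis=1) <= r_net).reshape(grid_shape)
        net = ball & gm
        if net.sum() < 4:
            raise ValueError("network blob fell outside gray matter; grid too small")
        networks.append(net)

    if n_seeds > 3 * n_networks:
        raise ValueError("too many seeds: at most 3 per network are supported")
    r_seed = max(1.0, r_net / 2.0)
    seeds: list[np.ndarray] = []
    seed_to_network: dict[int, int] = {}
    for s in range(n_seeds):
        net_idx = s % n_networks
        net = networks[net_idx]
        net_voxels = np.argwhere(net)
        target = net_voxels.mean(axis=0) + rng.normal(0.0, 0.5, size=3)
        ball = (np.linalg.norm(idx - target, axis=1) <= r_seed).reshape(grid_shape)
        seed = ball & net
        if not seed.any():  # jitter pushed the ball off the blob: use its peak voxel
            seed = np.zeros(grid_shape, dtype=bool)
            nearest = net_voxels[
                np.argmin(np.linalg.norm(net_voxels - target, axis=1))
            ]
            seed[tuple(nearest)] = True
        seeds.append(seed)
        seed_to_network[s] = net_idx

    atlas = PhantomAtlas(
        grid_shape=grid_shape,
        voxel_size=tuple(voxel_size),
        brain_mask=brain,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        edge_mask=edge,
        seed_masks=seeds,
        reference_networks=networks,
        seed_to_network=seed_to_network,
    )
    atlas.validate()
    return atlas


# ---------------------------------------------------------------------------
# Motion simulation
# ---------------------------------------------------------------------------


def _smooth_walk(rng, n, step_sd, sigma_frames=5.0) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, step_sd, size=(n, 3)), axis=0)
    return ndimage.gaussian_filter1d(walk, sigma=sigma_frames, axis=0)


def simulate_motion_trace(
    n_timepoints: int,
    tr: float,
    mode: str = "smooth",
    rng_seed: int = 0,
    amplitude_scale: float = 1.0,
) -> MotionTrace:
    """Generate a rigid-body trajectory.

    ``smooth`` produces the slow drifting motion of a compliant subject
    (median FWD well under 0.2 mm).  ``hf_tremor`` adds frame-to-frame
    jitter near the Nyquist frequency on top of the smooth baseline,
    reproducing the tremor/heavy-breathing phenotype: FWD exceeds 0.2 mm in
    most frames yet rarely exceeds 0.5 mm.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if mode not in ("smooth", "hf_tremor"):
        raise ValueError(f"unknown motion mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    trans = _smooth_walk(rng, n_timepoints, SMOOTH_STEP_MM)
    rots = _smooth_walk(rng, n_timepoints, SMOOTH_STEP_RAD)
    if mode == "hf_tremor":
        trans = trans + rng.normal(0.0, HF_TRANS_JITTER_MM, size=trans.shape)
        rots = rots + rng.normal(0.0, HF_ROT_JITTER_RAD, size=rots.shape)
    params = np.hstack([rots, trans]) * amplitude_scale
    return MotionTrace(params=params, tr=tr)


# ---------------------------------------------------------------------------
# Subject and cohort simulation
# ---------------------------------------------------------------------------


def band_limited_noise(
    rng: np.random.Generator,
    n_timepoints: int,
    tr: float,
    low_hz: float,
    high_hz: float,
    n_series: int = 1,
) -> np.ndarray:
    """White noise DFT-masked into [low_hz, high_hz], unit variance, T x n."""
    x = rng.standard_normal((n_series, n_timepoints))
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    spec = np.fft.rfft(x, axis=-1)
    spec[:, ~((freqs >= low_hz) & (freqs <= high_hz))] = 0.0
    out = np.fft.irfft(spec, n=n_timepoints, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (out / sd).T


def _unit(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject(
    atlas: PhantomAtlas,
    config: SimulationConfig,
    subject_seed: int,
    motion_mode: str = "smooth",
    subject_id: str | None = None,
) -> SyntheticSubject:
    """Simulate one acquisition on the phantom.

    The volume is the sum of: a flat baseline; band-limited network time
    courses painted on their masks; a motion artifact whose amplitude
    follows the FWD series and whose spatial weight decays exponentially
    with distance from the brain edge; physiological signals shared across
    WM, CSF and the whole brain; a slow polynomial drift; and white thermal
    noise.  A fraction ``shared_variance`` of each noise time course is a
    mixture of the network time courses, modeling neurovascular coupling of
    noise and signal.
    """
    T, tr = config.n_timepoints, config.tr
    m = atlas.n_networks
    rng = np.random.default_rng(subject_seed)

    motion = simulate_motion_trace(
        T, tr, motion_mode, rng_seed=int(rng.integers(2**31))
    )
    fwd = framewise_displacement(motion)

    net_tcs = band_limited_noise(rng, T, tr, *config.passband, n_series=m)

    # unique noise processes: six per-axis motion-magnitude series (the
    # artifact each motion axis induces scales with that axis' frame-to-frame
    # change) + three slow physiological signals.  Artifact series are scaled
    # by a fixed reference (the per-frame displacement scale of a tremor
    # subject), so low-motion subjects get proportionally little artifact.
    d = np.abs(np.diff(motion.params, axis=0, prepend=motion.params[:1]))
    d[:, :3] *= 50.0  # rotations linearized on the head sphere, as in FWD
    d = d - d.mean(axis=0)
    ref_scale = np.sqrt(1.0 - 2.0 / np.pi) * np.sqrt(2.0) * HF_TRANS_JITTER_MM
    artifact_base = d[:, [3, 4, 5, 0, 1, 2]] / ref_scale  # translations first

    def net_mixtures(n: int) -> np.ndarray:
        if m == 0:
            return np.zeros((T, n))
        w = rng.standard_normal((m, n))
        return np.apply_along_axis(_unit, 0, net_tcs @ w)

    # physiological signals: a common low-frequency core (network-coupled by
    # shared_variance — vascular fluctuations confound connectivity) that
    # dominates the global signal and feeds the WM/CSF compartments, which
    # is what makes WM/CSF mean regression a usable global-physio proxy
    kp = config.shared_variance
    physio_raw = band_limited_noise(rng, T, tr, 0.005, 0.15, n_series=3)
    g_core = np.sqrt(1.0 - kp**2) * physio_raw[:, 0] + kp * net_mixtures(1)[:, 0]
    beta = PHYSIO_COMMON_COUPLING
    wm_tc = np.sqrt(1.0 - beta**2) * physio_raw[:, 1] + beta * g_core
    csf_tc = np.sqrt(1.0 - beta**2) * physio_raw[:, 2] + beta * g_core
    global_tc = g_core
    physio_tcs = np.column_stack([wm_tc, csf_tc, global_tc])

    # motion-artifact series: per-axis magnitudes, coupled to the networks
    # (ka) and to the global physiological signal (rho: breathing moves the
    # head AND modulates global BOLD); couplings scale with the subject's
    # own motion level so still subjects get little artifact
    ka = config.artifact_network_coupling
    rho = config.artifact_physio_coupling
    sigma = artifact_base.std(axis=0)
    artifact_tcs = (
        np.sqrt(1.0 - ka**2 - rho**2) * artifact_base
        + ka * sigma * net_mixtures(6)
        + rho * sigma * global_tc[:, None]
    )
    noise_tcs = np.column_stack([artifact_tcs, physio_tcs])  # T x 9

    dist_in = ndimage.distance_transform_edt(atlas.brain_mask)
    edge_weight = np.where(
        atlas.brain_mask, np.exp(-dist_in / EDGE_DECAY_SCALE_VOX), 0.0
    )
    # spatially heterogeneous per-axis artifact gains: mostly-positive smooth
    # random fields, unit-normalized per voxel, so the artifact is genuinely
    # high-rank (no low-dimensional decomposition captures it exactly)
    fields = ndimage.gaussian_filter(
        rng.standard_normal((6, *atlas.grid_shape)), sigma=(0, 2.0, 2.0, 2.0)
    )
    fields /= fields.std()
    gains = 0.7 + 0.7 * fields
    gains /= np.linalg.norm(gains, axis=0, keepdims=True)

    x = np.linspace(-1.0, 1.0, T)
    drift_tc = sum(
        rng.standard_normal() * np.polynomial.legendre.Legendre.basis(p)(x)
        for p in range(1, 4)
    )
    drift_tc = _unit(drift_tc)

    data = np.zeros((*atlas.grid_shape, T))
    data += config.baseline
    for k in range(m):
        data[atlas.reference_networks[k]] += config.network_amplitude * net_tcs[:, k]
    artifact_field = np.einsum("jxyz,tj->xyzt", gains, artifact_tcs)
    data += config.motion_artifact_amplitude * edge_weight[..., None] * artifact_field
    data[atlas.wm_mask] += config.physio_amplitude * wm_tc
    data[atlas.csf_mask] += config.physio_amplitude * csf_tc
    data[atlas.brain_mask] += 0.5 * config.physio_amplitude * global_tc
    data[atlas.brain_mask] += config.drift_amplitude * drift_tc
    if config.thermal_sd > 0:
        data += rng.normal(0.0, config.thermal_sd, size=data.shape)

    volume = Volume4D(
        data=data,
        voxel_size=atlas.voxel_size,
        tr=tr,
        affine=np.diag([*atlas.voxel_size, 1.0]),
    )
    return SyntheticSubject(
        subject_id=subject_id or f"sub-{subject_seed}",
        volume=volume,
        motion=motion,
        motion_mode=motion_mode,
        truth_network_timecourses=net_tcs,
        truth_noise_timecourses=noise_tcs,
    )


def cohort_plan(config: SimulationConfig) -> list[dict]:
    """Deterministic per-subject seeds and motion modes for a cohort."""
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    ss = np.random.SeedSequence(config.rng_seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(config.n_subjects)]
    n_hf = int(round(config.hf_motion_fraction * config.n_subjects))
    order = np.random.default_rng(config.rng_seed).permutation(config.n_subjects)
    hf = np.zeros(config.n_subjects, dtype=bool)
    hf[order[:n_hf]] = True
    return [
        {
            "subject_id": f"sub-{i:03d}",
            "seed": seeds[i],
            "motion_mode": "hf_tremor" if hf[i] else "smooth",
        }
        for i in range(config.n_subjects)
    ]


def iter_cohort(atlas: PhantomAtlas, config: SimulationConfig):
    """Yield subjects one at a time (memory bounded by a single subject)."""
    for entry in cohort_plan(config):
        yield simulate_subject(
            atlas,
            config,
            entry["seed"],
            motion_mode=entry["motion_mode"],
            subject_id=entry["subject_id"],
        )


def simulate_cohort(
    atlas: PhantomAtlas,
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    keep_in_memory: bool = True,
) -> tuple[list[SyntheticSubject], dict]:
    """Simulate a cohort; optionally write NIfTI volumes + motion files.

    Returns the subjects (empty list when ``keep_in_memory`` is False) and a
    manifest describing every subject, its seed, motion mode, and the paths
    written.  The manifest is bit-identical across reruns of the same
    configuration.
    """
    plan = cohort_plan(config)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "subjects": [],
    }
    subjects: list[SyntheticSubject] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for entry in plan:
        subject = simulate_subject(
            atlas,
            config,
            entry["seed"],
            motion_mode=entry["motion_mode"],
            subject_id=entry["subject_id"],
        )
        record = dict(entry)
        if out_path is not None:
            record.update(write_subject(subject, out_path))
        manifest["subjects"].append(record)
        if keep_in_memory:
            subjects.append(subject)
    if out_path is not None:
        manifest_path = out_path / "manifest.json"
        _write_text(manifest_path, json.dumps(manifest, indent=2, sort_keys=True))
    return subjects, manifest


def _write_text(path: Path, text: str) -> None:
    try:
        path.write_text(text)
    except OSError as exc:
        raise OSError(f"failed to write {path}: {exc}") from exc


def write_subject(subject: SyntheticSubject, out_dir: Path) -> dict:
    """Write one subject's volume, motion file and ground truth; return paths."""
    import nibabel as nib

    sid = subject.subject_id
    paths = {
        "volume": f"{sid}_bold.nii",
        "motion": f"{sid}_motion.txt",
        "truth_networks": f"{sid}_truth_networks.txt",
        "truth_noise": f"{sid}_truth_noise.txt",
    }
    try:
        img = nib.Nifti1Image(
            subject.volume.data.astype(np.float32), subject.volume.affine
        )
        img.header.set_zooms((*subject.volume.voxel_size, subject.volume.tr))
        nib.save(img, out_dir / paths["volume"])
        save_motion_file(out_dir / paths["motion"], subject.motion)
        np.savetxt(out_dir / paths["truth_networks"], subject.truth_network_timecourses)
        np.savetxt(out_dir / paths["truth_noise"], subject.truth_noise_timecourses)
    except OSError as exc:
        raise OSError(f"failed to write subject {sid} under {out_dir}: {exc}") from exc
    return paths


def load_subject_volume(path: str | Path) -> Volume4D:
    """Read a 4D NIfTI file into a :class:`Volume4D`."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return Volume4D(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=float(zooms[3]) if len(zooms) > 3 else 1.0,
        affine=np.asarray(img.affine),
    )
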