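# Methods

## The phantom's generative model

Each synthetic subject is a 4D volume

```
Y(v,t) = B
       + Σ_k  1[v ∈ network_k] · a_net · n_k(t)
       + a_mot · w(v) · Σ_j g_j(v) · m_j(t)
       + a_phys · ( 1[v ∈ WM] · p_wm(t) + 1[v ∈ CSF] · p_csf(t)
                    + 0.5 · 1[v ∈ brain] · p_g(t) )
       + a_drift · 1[v ∈ brain] · d(t)
       + ε(v,t),     ε ~ N(0, σ_th²)
```

with baseline `B = 100` and all amplitudes in baseline-image units.

**Geometry.** The atlas is a set of concentric compartments on a cubic
grid: an ellipsoidal brain (semi-axes 0.42 of the grid), a CSF core (0.10),
a WM shell (0.22), a GM shell carrying the networks, and an edge shell
(brain minus its 2-voxel erosion). Network blobs sit on a Fibonacci
lattice over the mid-GM sphere — evenly spaced, deterministic for a fixed
seed, with an explicit packing check that raises when the requested count
cannot fit. Each seed is a small ball inside its assigned network
(seed *i* → network *i* mod M). Defaults mirror a 22-seed / 14-network
atlas at full scale and 6 seeds / 4 networks at desk scale.

**Network signals** `n_k` are unit-variance Gaussian processes DFT-masked
into the 0.01–0.08 Hz passband (their out-of-band power is exactly zero on
the DFT grid).

**Motion.** `smooth` trajectories are Gaussian-filtered random walks
(median FWD ≪ 0.2 mm). `hf_tremor` adds white frame-to-frame jitter
(translations sd 0.08 mm/axis, rotations 2·10⁻⁴ rad/axis), calibrated
analytically so FWD ≈ N(0.31 mm, 0.12 mm) on a 50 mm head sphere: most
frames exceed 0.2 mm, few exceed 0.5 mm — the tremor phenotype of older
cohorts. Half the cohort gets tremor by default.

**Motion artifact.** Six per-axis magnitude series
`m_j ∝ |Δp_j(t)|` (rotations linearized on the 50 mm sphere), scaled by a
fixed reference displacement so still subjects get proportionally little
artifact; the spatial weight is `w(v) = exp(−dist_to_edge / 2 voxels)`
(edge-concentrated), multiplied by smooth, mostly-positive per-voxel gain
fields `g_j` normalized to unit norm across axes. The per-voxel gains make
the artifact genuinely high-rank, like real spin-history effects.

**Couplings.** Three knobs plant the shared-variance structure of real
recordings, each expressed as a correlation coefficient applied to
unit-scale series:

| parameter | default | meaning |
|---|---|---|
| `shared_variance` | 0.5 | network coupling of the global physio core (vascular confounding of connectivity) |
| `artifact_physio_coupling` | 0.45 | breathing drives both head motion and global BOLD |
| `artifact_network_coupling` | 0.15 | weak direct network coupling of the artifact |

The WM and CSF compartment signals share the global physio core with
coefficient 0.6, which is what makes WM/CSF mean regression a usable
global-physio proxy — as it is in practice.

**Amplitude defaults** (baseline 100): networks 1.0 (≈ 1 % BOLD), motion
artifact 2.5 (dominates at the edge for tremor subjects), physio 0.7,
drift 1.0, thermal sd 1.0. These are plausibility choices, not estimates
of any particular cohort; they are exposed in `SimulationConfig`.

**Ground truth.** Every subject returns its planted network time courses,
the nine noise time courses (six artifact + WM/CSF/global physio), and
component labels. Regressing any voxel on the noise series plus drift
removes the planted contamination exactly (tested: edge residuals are
uncorrelated with FWD).

## What the phantom does and does not emulate

Emulated: band-limited network fluctuations, tremor-like motion with the
0.2/0.5 mm FWD profile, edge-concentrated motion-locked artifact, shared
WM/CSF/global physiology coupled to both networks and motion, polynomial
drift, thermal noise, paper-like timing (TR 2.5 s) and scalable geometry.

Not emulated: hemodynamic response shapes, EPI distortion, slice timing,
multi-site scanner effects, realistic component *classification* errors —
labels come from matching against the exact planted series. Passing tests
therefore validate the algebra and statistics of the pipeline and the
direction of shared-variance effects, not classifier behavior on real
data; see Limitations.

## Technique implementation notes

* All five techniques share one 4 mm-smoothed regression target and, for
  the component paths, one spatial ICA of the 6 mm-smoothed copy (the
  two-kernel workflow; kernels configurable, disable-able on tiny grids).
  The classifiers that would distinguish the AROMA paths from the
  SOCK-style path are inputs here, so a shared decomposition is the
  controlled comparison.
* Censored frames are spike-regressed, never deleted, so every technique
  returns a full-length series and all metrics use all frames.
* The bandpass (0.009–0.08 Hz) is a hard DFT mask applied after the
  confound regression in every technique. `build_design_matrix` can
  instead fold the bandpass into the design as out-of-band sine/cosine
  regressors (the 3dDeconvolve convention, simultaneous with censoring);
  at short desk-scale runs (T = 120, TR 2.5 s) that convention leaves
  rank-≈10 residuals whose correlation maps are estimation noise, so the
  pipeline uses the post-hoc filter for comparability across techniques.
* Oracle labeling matches ICA time courses against the planted
  **motion-artifact** series only (threshold |r| ≥ 0.6, a signal match must
  not beat the noise match). Motion-targeted classifiers do not remove
  physiological components; retaining them is what produces the
  characteristic high WM/CSF/false-positive connectivity of the AROMA
  paths. If no component reaches threshold (still subjects), the single
  best-matching component is flagged, since practical classifiers always
  find some motion component.
* ICA-AROMA-style partial regression: `β = pinv(M_centered) Y_centered`,
  `Y_clean = Y − M_noise β_noise`; ill-conditioned mixing falls back to the
  pseudoinverse with a logged condition number.

## Numerical choices

* **OLS**: designs are mean-centered; constant columns are dropped with a
  warning; minimum-norm `lstsq` handles rank deficiency; voxel means are
  restored. Residuals are orthogonal to the design to 10⁻⁶ and the
  operation is idempotent.
* **FastICA**: model order defaults to the PCA order retaining 95 %
  variance, overridable; the benchmark pipeline fixes 12 components
  (≈ T/10, a typical single-run order at desk scale, and the order at
  which every phantom subject converges). Convergence uses a
  deterministic ladder — two attempts at tol 10⁻⁴, two at 10⁻³, three at
  10⁻² with reseeded initial rotations — because near-Gaussian residual
  directions make the tightest tolerance unreachable on noisy data;
  exhausting the ladder raises, withholding partial results. Mixing
  columns are variance-normalized.
* **Fisher z**: r clipped at 1 − 10⁻⁷ before atanh so means stay finite.
* **GMM threshold**: two components on signed z, deterministic init with
  means at the 25th/95th percentiles and weights (0.9, 0.1) — the active
  class is an upper-tail minority, and a symmetric init converges to a
  wrong local optimum that splits the null bulk. EM runs to tol 10⁻⁶.
  The threshold is the smallest observed z above the lower component's
  mean with upper-component posterior > 0.5. Near-constant maps or a
  component weight < 10⁻³ return the degenerate "no suprathreshold
  voxels" result.
* **Smoothness**: six spheres at radii j/7 of the maximum normalized
  frequency radius (per-axis Nyquist = 1), DC excluded; each radius
  contributes mean|F| inside / mean|F| outside, and the statistic is their
  mean, oriented so that Gaussian smoothing increases it. The absolute
  scale is a convention of this normalization; only orderings are
  meaningful.
* **Reproducibility pseudo-z**: per-seed mean of the permutation diagonal
  correlations standardized by the pooled off-diagonal null (mean/sd).
  Odd cohorts split floor/ceil. Cohorts below 4 subjects are rejected.
* **Mann-Whitney U**: SciPy's exact method for small tie-free samples,
  tie- and continuity-corrected normal approximation otherwise; U is
  reported for the first-listed group. Bonferroni multiplies by the
  k(k−1)/2 pairs of the metric (per-metric family, matching per-metric
  reporting). All-identical data returns H = 0, p = 1 by convention.
* **Ranking ties**: every technique tied at the best (worst) mean is
  flagged best (worst).
* **Determinism**: subject seeds spawn from a root `SeedSequence`; the
  tremor/smooth assignment is an exact count (`round(fraction · n)`) on a
  seeded permutation; GMM/ICA seeds derive from the run seed; tables are
  written with fixed float formatting, so reruns are byte-identical.

## Problem sizes

The shipped benchmark runs 12 subjects on a 24³ grid with 120 frames,
6 seeds / 4 networks, and 500 split-half permutations (≈ 2 minutes on one
CPU); the generator streams cohorts subject-by-subject, so memory is
bounded by a single subject at any cohort size, and full-scale geometry
(64 × 64 in-plane, 288 frames, hundreds of subjects) is a config change.

## Limitations

* Component labels are oracle matches against planted series. With exact
  labels, any artifact the decomposition captures is removed by *both*
  regression variants (the joint-fit attribution is exact), so the
  benchmark reproduces the shared-variance direction of the partial-vs-
  full difference in false-positive/WM/CSF connectivity, but not the
  large edge-activity and reproducibility penalties that non-aggressive
  cleanup shows on real data, where imperfect classification and
  artifact heterogeneity drive the gap. On this phantom the censoring
  technique retains the most in-band seed-coupled artifact at the edge.
* Reproducibility pseudo-z values at desk scale (≈ 2.5) are not
  comparable to full-scale cohort values; the statistic grows with cohort
  size and seed count.
* The smoothness statistic's absolute scale is implementation-defined;
  compare only within a run.
* tDOF percentages for the component techniques follow the fixed model
  order (12 of 120 ≈ 10 % ceiling), not a data-driven order estimate.
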