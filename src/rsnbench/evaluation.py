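"""Technique comparison, ranking, and end-to-end pipeline orchestration.

Techniques are compared per metric with a Kruskal-Wallis test across all
groups and pairwise Mann-Whitney U tests, Bonferroni-corrected within the
metric's family of pairs.  Rankings respect each metric's direction of
goodness (higher reproducibility is better; lower edge activity is better).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import qc
from .connectivity import gmm_threshold, seed_correlation_map
from .denoise import TECHNIQUES, TechniqueOptions, apply_technique
from .synthetic import (
    PhantomAtlas,
    SimulationConfig,
    SyntheticSubject,
    iter_cohort,
    make_phantom_atlas,
)

logger = logging.getLogger(__name__)

#: Direction of goodness per metric: True when larger values are better.
METRIC_DIRECTION = {
    "reproducibility_z": True,
    "identifiability_z": True,
    "smoothness": True,
    "tp_conn_r": True,
    "edge_activity_pct": False,
    "tdof_fraction": False,
    "fp_conn_r": False,
    "wm_conn_r": False,
    "csf_conn_r": False,
}


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p on k-1 df.

    All-identical data across all groups yields (H=0, p=1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_mannwhitney_bonferroni(
    groups: list, labels: list[str]
) -> pd.DataFrame:
    """All pairwise Mann-Whitney U tests with Bonferroni correction.

    ``u`` is the U statistic of the first-listed group (number of pairs
    where a value from ``tech_a`` exceeds one from ``tech_b``, ties counted
    half).  Exact p-values are used for small tie-free samples, the
    tie- and continuity-corrected normal approximation otherwise; the family
    for correction is the k(k-1)/2 pairs of this metric.
    """
    if len(groups) != len(labels):
        raise ValueError("groups and labels differ in length")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    k = len(arrays)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.mannwhitneyu(
                arrays[i], arrays[j], alternative="two-sided", method="auto"
            )
            rows.append(
                {
                    "tech_a": labels[i],
                    "tech_b": labels[j],
                    "u": float(res.statistic),
                    "p_raw": float(res.pvalue),
                    "p_bonferroni": float(min(1.0, res.pvalue * n_pairs)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Per-metric comparison across techniques."""

    metric: str
    higher_is_better: bool
    summary: pd.DataFrame  # technique, mean, sd, n
    best: list[str]
    worst: list[str]
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame


def rank_techniques(table: pd.DataFrame) -> dict[str, ComparisonResult]:
    """Compare techniques on every metric in a long-format table.

    ``table`` has columns ``technique``, ``metric``, ``value``.  For each
    metric: per-technique mean +/- sd, best/worst flags by the metric's
    direction of goodness (ties flag every tied technique), and the
    attached Kruskal-Wallis and pairwise Mann-Whitney tests (attached only
    when every technique has at least 2 values and there are at least 2
    techniques).
    """
    required = {"technique", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    results: dict[str, ComparisonResult] = {}
    for metric, sub in table.groupby("metric", sort=True):
        if metric not in METRIC_DIRECTION:
            raise ValueError(f"no direction of goodness defined for metric {metric!r}")
        higher = METRIC_DIRECTION[metric]
        summary = (
            sub.groupby("technique")["value"]
            .agg(mean="mean", sd="std", n="size")
            .reset_index()
            .sort_values("technique")
            .reset_index(drop=True)
        )
        best_val = summary["mean"].max() if higher else summary["mean"].min()
        worst_val = summary["mean"].min() if higher else summary["mean"].max()
        best = sorted(summary.loc[np.isclose(summary["mean"], best_val), "technique"])
        worst = sorted(summary.loc[np.isclose(summary["mean"], worst_val), "technique"])
        labels = list(summary["technique"])
        groups = [sub.loc[sub["technique"] == t, "value"].to_numpy() for t in labels]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            h, p = kruskal_wallis(groups)
            pairwise = pairwise_mannwhitney_bonferroni(groups, labels)
        else:
            h, p = float("nan"), float("nan")
            pairwise = pd.DataFrame(
                columns=["tech_a", "tech_b", "u", "p_raw", "p_bonferroni"]
            )
        results[metric] = ComparisonResult(
            metric=metric,
            higher_is_better=higher,
            summary=summary,
            best=best,
            worst=worst,
            kruskal_h=h,
            kruskal_p=p,
            pairwise=pairwise,
        )
    return results


def long_format(metrics: pd.DataFrame, repro: pd.DataFrame | None = None) -> pd.DataFrame:
    """Melt the subject-level metrics table (plus per-seed reproducibility).

    Subject-level metrics contribute one value per subject; reproducibility,
    being a cohort-level quantity, contributes one value per seed from the
    ``repro`` table (columns technique, seed, pseudo_z) when given.
    """
    value_cols = [
        c for c in qc.METRIC_COLUMNS
        if c not in ("subject_id", "technique", "reproducibility_z")
    ]
    long = metrics.melt(
        id_vars=["technique"],
        value_vars=value_cols,
        var_name="metric",
        value_name="value",
    )
    if repro is not None:
        extra = repro.rename(columns={"pseudo_z": "value"})[["technique", "value"]]
        extra.insert(1, "metric", "reproducibility_z")
        long = pd.concat([long, extra], ignore_index=True)
    return long


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end benchmark run."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_seeds: int = 6
    n_networks: int = 4
    atlas_seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    techniques: tuple[str, ...] = TECHNIQUES
    fwd_cutoff_mm: float = 0.5
    detrend_order: int = 3
    band: tuple[float, float] = (0.009, 0.08)
    ica_fwhm_mm: float | None = 6.0
    data_fwhm_mm: float | None = 4.0
    n_components: int | None = 12
    label_min_abs_r: float = 0.6
    n_permutations: int = 500

    def __post_init__(self) -> None:
        unknown = [t for t in self.techniques if t not in TECHNIQUES]
        if unknown:
            raise ValueError(
                f"unknown technique(s) {unknown} in field 'techniques'; "
                f"valid names: {list(TECHNIQUES)}"
            )
        if not self.techniques:
            raise ValueError("field 'techniques' must list at least one technique")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", {})
        if isinstance(sim, dict):
            sim = {
                k: (tuple(v) if k == "passband" else v) for k, v in sim.items()
            }
            sim = SimulationConfig(**sim)
        for key in ("grid_shape", "band", "techniques"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)

        def plain(x):
            if isinstance(x, tuple):
                return [plain(v) for v in x]
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            return x

        return plain(d)

    def technique_options(self, subject: SyntheticSubject) -> TechniqueOptions:
        return TechniqueOptions(
            fwd_cutoff_mm=self.fwd_cutoff_mm,
            detrend_order=self.detrend_order,
            band=self.band,
            ica_fwhm_mm=self.ica_fwhm_mm,
            data_fwhm_mm=self.data_fwhm_mm,
            n_components=self.n_components,
            rng_seed=self.simulation.rng_seed,
            noise_timecourses=subject.truth_artifact_timecourses,
            signal_timecourses=subject.truth_network_timecourses,
            label_min_abs_r=self.label_min_abs_r,
        )


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    reproducibility: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    failures: list[str]


def _subject_maps(
    volume, atlas: PhantomAtlas
) -> np.ndarray:
    """Per-seed z maps flattened over the brain mask: (S, V)."""
    out = []
    for s, seed_mask in enumerate(atlas.seed_masks):
        rsn = seed_correlation_map(volume, seed_mask, atlas.brain_mask, seed_index=s)
        out.append(rsn.zmap[atlas.brain_mask])
    return np.asarray(out)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Simulate a cohort, run every technique, compute metrics, rank.

    Per-subject/technique failures are logged and excluded; if more than
    10% of cells fail the run raises.  With ``out_dir`` the metrics,
    per-seed reproducibility, comparison report and a run log are written;
    reruns of the same config produce byte-identical tables.
    """
    atlas = make_phantom_atlas(
        config.grid_shape, config.n_seeds, config.n_networks, config.atlas_seed
    )
    sim = config.simulation
    gmm_seed = sim.rng_seed + 1

    zmaps: dict[str, list[np.ndarray]] = {t: [] for t in config.techniques}
    rows: list[qc.MetricRecord] = []
    partial: list[dict] = []
    failures: list[str] = []
    n_cells = 0

    for subject in iter_cohort(atlas, sim):
        opts = config.technique_options(subject)
        for technique in config.techniques:
            n_cells += 1
            try:
                cleaned, tdof = apply_technique(subject, technique, atlas, opts)
                flat = _subject_maps(cleaned, atlas)
            except Exception as exc:  # noqa: BLE001 — isolate per-cell failures
                logger.warning(
                    "subject %s technique %s failed: %s",
                    subject.subject_id,
                    technique,
                    exc,
                )
                failures.append(f"{subject.subject_id}/{technique}: {exc}")
                continue
            zmaps[technique].append(flat)

            ident, edge, smooth, subs = [], [], [], []
            for s in range(atlas.n_seeds):
                zmap = np.zeros(atlas.grid_shape)
                zmap[atlas.brain_mask] = flat[s]
                ref = atlas.reference_networks[atlas.seed_to_network[s]]
                ident.append(qc.identifiability(zmap, ref, atlas.brain_mask))
                thr = gmm_threshold(zmap, atlas.brain_mask, rng_seed=gmm_seed)
                edge.append(qc.edge_activity(thr.mask, atlas.edge_mask))
                smooth.append(qc.spatial_smoothness(zmap))
                subs.append(qc.connectivity_subscores(zmap, atlas, ref))
            subs_mean = np.mean(np.asarray(subs), axis=0)
            partial.append(
                {
                    "subject_id": subject.subject_id,
                    "technique": technique,
                    "identifiability_z": float(np.mean(ident)),
                    "edge_activity_pct": float(np.mean(edge)),
                    "smoothness": float(np.mean(smooth)),
                    "tdof_fraction": tdof.fraction_lost,
                    "tp_conn_r": float(subs_mean[0]),
                    "fp_conn_r": float(subs_mean[1]),
                    "wm_conn_r": float(subs_mean[2]),
                    "csf_conn_r": float(subs_mean[3]),
                }
            )

    if failures and len(failures) > 0.1 * n_cells:
        raise RuntimeError(
            f"{len(failures)} of {n_cells} subject/technique cells failed: "
            + "; ".join(failures)
        )

    repro_rows = []
    repro_by_tech: dict[str, np.ndarray] = {}
    for technique in config.techniques:
        stack = np.asarray(zmaps[technique])  # n_ok x S x V
        if stack.shape[0] >= 4:
            res = qc.split_half_reproducibility(
                stack, config.n_permutations, rng_seed=sim.rng_seed
            )
            repro_by_tech[technique] = res.pseudo_z
            for s, z in enumerate(res.pseudo_z):
                repro_rows.append(
                    {"technique": technique, "seed": s, "pseudo_z": float(z)}
                )
    repro = pd.DataFrame(repro_rows, columns=["technique", "seed", "pseudo_z"])

    for row in partial:
        tech_z = repro_by_tech.get(row["technique"])
        row["reproducibility_z"] = (
            float(np.mean(tech_z)) if tech_z is not None else float("nan")
        )
    records = [qc.MetricRecord(**row) for row in partial]
    metrics = qc.collect_metrics(records)
    if not failures:  # failed cells are already reported above
        qc.check_complete(metrics)

    comparisons = rank_techniques(long_format(metrics, repro))
    result = PipelineResult(metrics, repro, comparisons, failures)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def comparison_report(comparisons: dict[str, ComparisonResult]) -> str:
    """Markdown summary: per-metric means, best/worst, and test p-values."""
    lines = ["# Technique comparison", ""]
    for metric, res in comparisons.items():
        direction = "higher is better" if res.higher_is_better else "lower is better"
        lines.append(f"## {metric} ({direction})")
        lines.append("")
        lines.append("| technique | mean | sd | n |  |")
        lines.append("|---|---|---|---|---|")
        for _, r in res.summary.iterrows():
            flag = (
                "best" if r["technique"] in res.best else
                "worst" if r["technique"] in res.worst else ""
            )
            lines.append(
                f"| {r['technique']} | {r['mean']:.4g} | {r['sd']:.4g} "
                f"| {int(r['n'])} | {flag} |"
            )
        lines.append("")
        lines.append(
            f"Kruskal-Wallis H = {res.kruskal_h:.4g}, p = {res.kruskal_p:.3g}"
        )
        if len(res.pairwise):
            sig = res.pairwise[res.pairwise["p_bonferroni"] < 0.05]
            lines.append(
                f"; {len(sig)} of {len(res.pairwise)} pairwise tests significant "
                "after Bonferroni."
            )
        lines.append("")
    return "\n".join(lines)


def _write_outputs(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    qc.write_metrics(result.metrics, out / "metrics.tsv")
    result.reproducibility.to_csv(
        out / "reproducibility.tsv", sep="\t", index=False, float_format="%.10g"
    )
    frames = [
        res.pairwise.assign(metric=metric)
        for metric, res in result.comparisons.items()
        if len(res.pairwise)
    ]
    pairwise = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["tech_a", "tech_b", "u", "p_raw", "p_bonferroni", "metric"]
        )
    )
    pairwise.to_csv(
        out / "comparisons.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (out / "report.md").write_text(comparison_report(result.comparisons))
    cfg = config.to_dict()
    log = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "failures": result.failures,
        "n_metric_rows": int(len(result.metrics)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
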