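"""End-to-end orchestration: simulate -> featurize -> reduce -> cluster -> analyze.

Each stage is a plain function that consumes the previous stage's in-memory
artifact and persists its own outputs under the configured output directory,
so the pipeline can be rerun stage-by-stage from cached artifacts (the CLI
does exactly that) and identical configs with identical seeds give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClusterReport,
    assign,
    cluster_weights,
    fit_gmm,
    populations_by_condition,
    representative_frames,
    scan_k,
)
from .featurize import FeatureMatrix, distance_features, pick_feature_atoms
from .geometry import (
    average_structure,
    classify_open_closed,
    domain_rmsd,
    fraction_below,
    internal_rmsd,
    min_interdomain_distance,
    superpose_on_core,
)
from .reduce import PCAModel, ReducedSpace, fit_pca, n_components_for_threshold, project
from .structure_model import DomainMap, Trajectory, read_trajectory, write_pdb
from .synthetic_data import (
    GroundTruth,
    closedlike_ensemble,
    generate_trajectory,
    openlike_ensemble,
    save_run,
    two_state_demo,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

_ENSEMBLES = {
    "open_like": openlike_ensemble,
    "closed_like": closedlike_ensemble,
    "two_state": two_state_demo,
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline invocation (one system type).

    Defaults follow the reference analysis settings: CA picking stride 25,
    80% variance-explained threshold, K scanned over 2-8, and an 8 A
    (alternatively 10 A) minimum-distance threshold for the closed-contact
    state.
    """

    ensemble: str = "two_state"  # open_like | closed_like | two_state | none
    input_trajectories: list[str] = field(default_factory=list)
    domain_map: str | dict | None = None
    stride: int = 25
    variance_threshold: float = 0.80
    k_min: int = 2
    k_max: int = 8
    k_select: str = "elbow"  # elbow | silhouette | an integer K
    n_init: int = 10
    distance_pair: tuple[str, str] = ("CTD", "tower")
    distance_threshold: float = 8.0
    seed: int = 0
    frames_per_run: int | None = None
    runs_per_condition: int | None = None
    outdir: str = "results/run"
    write_trajectories: bool = False
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "distance_pair" in raw:
            raw["distance_pair"] = tuple(raw["distance_pair"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["distance_pair"] = list(self.distance_pair)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    def resolve_domain_map(self) -> DomainMap | None:
        if self.domain_map is None:
            return None
        if isinstance(self.domain_map, dict):
            return DomainMap({k: tuple(v) for k, v in self.domain_map.items()})
        return DomainMap.from_yaml(self.domain_map)

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["distance_pair"] = list(self.distance_pair)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs written so far are preserved on disk."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig):
    """Generate (or load) the input trajectories and ground truth."""
    out = _outdir(config)
    if config.input_trajectories:
        dmap = config.resolve_domain_map()
        if dmap is None:
            raise ValueError("a domain map is required for external trajectories")
        trajs = [read_trajectory(p) for p in config.input_trajectories]
        return trajs, [], dmap

    if config.ensemble not in _ENSEMBLES:
        raise ValueError(f"unknown ensemble {config.ensemble!r}")
    kwargs: dict = {"seed": config.seed}
    if config.frames_per_run is not None:
        kwargs["frames_per_run"] = config.frames_per_run
    if config.runs_per_condition is not None:
        kwargs["runs_per_condition"] = config.runs_per_condition
    spec = _ENSEMBLES[config.ensemble](**kwargs)
    runs = generate_trajectory(spec)
    trajs = [t for t, _ in runs]
    truths = [g for _, g in runs]
    if config.write_trajectories:
        rundir = out / "runs"
        for traj, truth in runs:
            save_run(traj, truth, rundir)
    labels = pd.concat(
        [
            pd.DataFrame(
                {
                    "run_id": g.run_id,
                    "condition": g.condition,
                    "frame": np.arange(len(g.labels)),
                    "state": g.labels,
                }
            )
            for g in truths
        ],
        ignore_index=True,
    )
    labels.to_csv(out / "ground_truth.csv", index=False)
    return trajs, truths, spec.domain_map


def stage_featurize(config: PipelineConfig, trajectories: list[Trajectory]) -> FeatureMatrix:
    """Strided CA selection and pooled distance features."""
    out = _outdir(config)
    atoms = pick_feature_atoms(trajectories[0].topology, config.stride)
    fm = distance_features(trajectories, atoms)
    fm.save(out / "features")
    logger.info(
        "featurize: %d atoms -> %d features over %d frames",
        len(atoms), fm.n_features, fm.n_frames,
    )
    return fm


def stage_reduce(config: PipelineConfig, fm: FeatureMatrix):
    """PCA fit, component selection at the variance threshold, projection."""
    out = _outdir(config)
    model = fit_pca(fm)
    m = n_components_for_threshold(model, config.variance_threshold)
    reduced = project(model, fm, m)
    model.save(out / "pca")
    np.savez_compressed(out / "scores.npz", scores=reduced.scores, m=m)
    logger.info(
        "reduce: %d components explain >= %.0f%% variance",
        m, 100 * config.variance_threshold,
    )
    return model, m, reduced


def stage_cluster(
    config: PipelineConfig,
    reduced: ReducedSpace,
    trajectories: list[Trajectory] | None = None,
):
    """K scan, model choice, assignment, populations, representative frames."""
    out = _outdir(config)
    selection = scan_k(
        reduced,
        k_min=config.k_min,
        k_max=config.k_max,
        seed=config.seed,
        n_init=config.n_init,
    )
    if isinstance(config.k_select, int):
        chosen_k = config.k_select
    elif config.k_select == "silhouette":
        chosen_k = selection.best_silhouette_k
    else:
        chosen_k = selection.elbow_k if selection.elbow_k is not None else selection.table["K"].iloc[0]
    chosen_k = int(chosen_k)
    model = selection.models.get(chosen_k) or fit_gmm(
        reduced, chosen_k, seed=config.seed, n_init=config.n_init
    )
    labels = assign(model, reduced)
    weights = cluster_weights(labels, K=model.K)
    populations = populations_by_condition(labels, reduced.frame_meta)
    reps = representative_frames(model, reduced, labels)
    report = ClusterReport(labels, weights, populations, reps, model)

    selection.table.to_csv(out / "selection.csv", index=False)
    frame_table = reduced.frame_meta.copy()
    frame_table["label"] = labels
    frame_table.to_csv(out / "cluster_report.csv", index=False)
    populations.to_csv(out / "populations.csv")
    summary = {
        "chosen_k": chosen_k,
        "elbow_k": selection.elbow_k,
        "best_silhouette_k": selection.best_silhouette_k,
        "second_best_silhouette_k": selection.second_best_silhouette_k,
        "weights": weights.tolist(),
        "representative_frames": {str(k): int(v) for k, v in reps.items()},
    }
    (out / "cluster_summary.json").write_text(json.dumps(summary, indent=2))

    if trajectories is not None:
        offsets = np.cumsum([0] + [t.n_frames for t in trajectories])
        repdir = out / "representatives"
        repdir.mkdir(exist_ok=True)
        for k, global_frame in reps.items():
            run = int(np.searchsorted(offsets, global_frame, side="right") - 1)
            local = global_frame - offsets[run]
            write_pdb(trajectories[run].frame(local), repdir / f"cluster_{k}.pdb")
    return selection, report


def stage_analyze(
    config: PipelineConfig,
    trajectories: list[Trajectory],
    domain_map: DomainMap,
):
    """Core-aligned per-domain RMSD, minimum interdomain distances, states."""
    out = _outdir(config)
    topology = trajectories[0].topology
    core = domain_map.atom_indices(topology, "FPT")
    reference = topology

    aligned = [superpose_on_core(t, core, reference) for t in trajectories]
    pooled = Trajectory(
        topology,
        np.concatenate([t.coords for t in aligned], axis=0),
        run_id="pooled",
    )
    avg = average_structure(pooled, core)

    domains = [d for d in ("EN", "tower", "FPT", "wrist", "CTD") if d == "FPT" or d in domain_map]
    if not domains:
        domains = domain_map.names()
    rmsd_rows = []
    for name in domains:
        idx = domain_map.atom_indices(topology, name)
        for ref_kind, ref in (("initial", reference), ("average", avg)):
            series = domain_rmsd(pooled, ref, idx, domain=name, reference_kind=ref_kind)
            rmsd_rows.append(
                {"domain": name, "reference": ref_kind, "mean": series.mean, "sd": series.sd}
            )
        internal = internal_rmsd(pooled, idx, reference, domain=name)
        rmsd_rows.append(
            {"domain": name, "reference": "internal", "mean": internal.mean, "sd": internal.sd}
        )
    rmsd_table = pd.DataFrame(rmsd_rows)
    rmsd_table.to_csv(out / "rmsd_domains.csv", index=False)

    a, b = config.distance_pair
    idx_a = domain_map.atom_indices(topology, a)
    idx_b = domain_map.atom_indices(topology, b)
    dist_rows = []
    for traj in trajectories:  # distances are rigid-motion invariant: raw frames
        series = min_interdomain_distance(traj, idx_a, idx_b, pair=(a, b))
        states = classify_open_closed(series, config.distance_threshold)
        dist_rows.append(
            pd.DataFrame(
                {
                    "run_id": traj.run_id,
                    "condition": traj.condition,
                    "frame": np.arange(traj.n_frames),
                    "min_distance": series.values,
                    "state": states,
                }
            )
        )
    distances = pd.concat(dist_rows, ignore_index=True)
    distances.to_csv(out / "distances.csv", index=False)
    contact_fraction = fraction_below(
        distances["min_distance"].to_numpy(), config.distance_threshold
    )
    analysis = {
        "distance_pair": [a, b],
        "distance_threshold": config.distance_threshold,
        "contact_fraction": contact_fraction,
        "rmsd_mean_initial": {
            row["domain"]: row["mean"]
            for _, row in rmsd_table[rmsd_table["reference"] == "initial"].iterrows()
        },
    }
    (out / "analysis_summary.json").write_text(json.dumps(analysis, indent=2))
    return rmsd_table, distances, analysis


def stage_report(config: PipelineConfig, results: dict) -> Path:
    """Write the run manifest (and optional elbow/silhouette figure)."""
    out = _outdir(config)
    manifest = {
        "package_version": __version__,
        "config": {**dataclasses.asdict(config), "distance_pair": list(config.distance_pair)},
        "config_hash": config.hash(),
        "seed": config.seed,
        "numpy_version": np.__version__,
        "results": {
            k: v for k, v in results.items() if isinstance(v, (int, float, str, list, dict, type(None)))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if config.make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        table = pd.read_csv(out / "selection.csv")
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(table["K"], table["bic"], "o-")
        axes[0].set(xlabel="K", ylabel="BIC", title="Elbow scan")
        axes[1].plot(table["K"], table["silhouette"], "o-")
        axes[1].set(xlabel="K", ylabel="mean silhouette", title="Silhouette scan")
        fig.tight_layout()
        fig.savefig(out / "model_selection.png", dpi=120)
        plt.close(fig)
    return out / "manifest.json"


# ---------------------------------------------------------------------------
# End to end
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; any failure names the stage and keeps outputs."""
    t0 = time.time()
    results: dict = {}
    stage = "simulate"
    try:
        trajs, truths, dmap = stage_simulate(config)
        results["n_runs"] = len(trajs)
        results["n_frames"] = int(sum(t.n_frames for t in trajs))

        stage = "featurize"
        fm = stage_featurize(config, trajs)
        results["n_feature_atoms"] = int(len(fm.feature_atoms))
        results["n_features"] = int(fm.n_features)

        stage = "reduce"
        pca_model, m, reduced = stage_reduce(config, fm)
        results["n_components"] = int(m)

        stage = "cluster"
        selection, report = stage_cluster(config, reduced, trajs)
        results["chosen_k"] = int(report.model.K)
        results["elbow_k"] = selection.elbow_k
        results["best_silhouette_k"] = selection.best_silhouette_k
        results["weights"] = report.weights.tolist()

        stage = "analyze"
        rmsd_table, distances, analysis = stage_analyze(config, trajs, dmap)
        results["contact_fraction"] = analysis["contact_fraction"]

        stage = "report"
        manifest = stage_report(config, results)
        results["manifest"] = str(manifest)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineStageError(stage, exc) from exc
    results["elapsed_s"] = round(time.time() - t0, 2)
    logger.info("pipeline finished in %.1fs: %s", results["elapsed_s"], config.outdir)
    return results
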