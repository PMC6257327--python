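"""End-to-end analysis pipeline: one config in, a bundle of artifacts out.

Orchestrates the full decomposition workflow over a trajectory: per-frame
energy matrix -> summary statistics -> Schlitter entropies -> stage
segmentation -> hydrogen-bond matrices -> RMSD dissimilarity matrices ->
contact map -> per-frame dimer classification, plus a reproducibility
manifest.  Every step is logged; a failing step aborts with its name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (
    energy_matrix, entropy_correction, schlitter_entropy, trajectory_summary,
)
from .constants import DEFAULT_TEMPERATURE
from .model_io import (
    Topology, Trajectory, read_forcefield, read_topology, read_trajectory,
    sample_frames, select_chain,
)
from .solvation import SolvationConfig
from .structure import (
    classify_dimer_conformation, hbond_density, hbond_occupancy,
    hbond_presence_matrix, rmsd_dissimilarity_matrix, sidechain_contact_map,
)
from .timeseries import moving_average, normalize_series, segment_stages

__all__ = ["AnalysisConfig", "run_pipeline"]

log = logging.getLogger("dimerpbsa")


@dataclass
class AnalysisConfig:
    topology: str
    trajectory: str
    params: str
    out_dir: str
    temperature: float = DEFAULT_TEMPERATURE
    interval_ps: float | None = None   # resample interval; None keeps all frames
    window_ns: float | None = None     # trailing window; None keeps all frames
    engine: str = "gb"
    n_sphere_points: int = 960
    grid_spacing: float = 0.5
    grid_padding: float = 12.0
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    contact_cutoff: float = 6.5
    smoothing_window: int = 101
    stage_window: int | None = None    # extremum neighborhood; None -> smoothing
    rmsd_matrices: bool = True
    classify: bool = True
    plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def solvation_config(self) -> SolvationConfig:
        return SolvationConfig(
            engine=self.engine,
            n_sphere_points=self.n_sphere_points,
            grid_spacing=self.grid_spacing,
            grid_padding=self.grid_padding,
        )


def _load_inputs(cfg: AnalysisConfig):
    topo = read_topology(Path(cfg.topology).read_text())
    traj = read_trajectory(cfg.trajectory, topo)
    ff = read_forcefield(cfg.params, topo)
    if cfg.interval_ps is not None and cfg.window_ns is not None:
        traj = sample_frames(traj, cfg.interval_ps, cfg.window_ns)
    return topo, traj, ff


def _stage_step(matrix: pd.DataFrame, cfg: AnalysisConfig):
    window = cfg.smoothing_window
    if window >= len(matrix):
        window = max(1, (len(matrix) // 2) * 2 - 1)
    de_mm = moving_average(normalize_series(matrix["dE_MM"].to_numpy()), window)
    de_sol = moving_average(normalize_series(matrix["dE_sol"].to_numpy()), window)
    stage_window = cfg.stage_window or window
    stage_window = min(stage_window, (len(matrix) - 1) // 2)
    comp = matrix[[c for c in matrix.columns if c != "time_ps"]]
    return segment_stages(de_mm, de_sol, window=stage_window, components=comp)


def run_pipeline(cfg: AnalysisConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of the artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.random.seed(cfg.seed & 0x7FFFFFFF)  # plotting order etc.; analyses are deterministic
    artifacts: dict[str, Path] = {}
    stage = "load inputs"
    try:
        topo, traj, ff = _load_inputs(cfg)
        sol_cfg = cfg.solvation_config()
        log.info("loaded %d atoms, %d frames", topo.n_atoms, traj.n_frames)

        stage = "energy matrix"
        matrix = energy_matrix(traj, ff, sol_cfg)
        artifacts["energy_matrix"] = out / "energy_matrix.csv"
        matrix.to_csv(artifacts["energy_matrix"], index=False)
        log.info("energy matrix: %d frames x %d components", *matrix.shape)

        stage = "summary"
        summary = trajectory_summary(matrix, cfg.temperature)
        artifacts["summary"] = out / "summary.csv"
        summary.as_frame().to_csv(artifacts["summary"])

        stage = "entropy"
        sels = {tag: select_chain(topo, tag) for tag in ("complex", "A", "B")}
        ent = {
            tag: schlitter_entropy(traj, sel, temperature=cfg.temperature)
            for tag, sel in sels.items()
        }
        corr = entropy_correction(
            ent["complex"].minus_t_s, ent["A"].minus_t_s, ent["B"].minus_t_s
        )
        artifacts["entropy"] = out / "entropy.json"
        artifacts["entropy"].write_text(json.dumps(
            {
                **{tag: {"s": e.s, "minus_t_s": e.minus_t_s} for tag, e in ent.items()},
                "minus_t_delta_s": corr,
                "temperature": cfg.temperature,
            },
            indent=1,
        ))

        stage = "stage segmentation"
        stages = _stage_step(matrix, cfg)
        artifacts["stages"] = out / "stages.csv"
        rows = []
        for b in stages.boundaries:
            rows.append({"boundary_frame": b,
                         "time_ns": matrix["time_ps"].iloc[b] / 1000.0})
        pd.DataFrame(rows, columns=["boundary_frame", "time_ns"]).to_csv(
            artifacts["stages"], index=False)
        if stages.stage_means is not None:
            artifacts["stage_means"] = out / "stage_means.csv"
            stages.stage_means.to_csv(artifacts["stage_means"])

        stage = "hydrogen bonds"
        presence = hbond_presence_matrix(
            traj, dist_cutoff=cfg.hbond_distance, angle_cutoff=cfg.hbond_angle)
        artifacts["hbond_presence"] = out / "hbond_presence.csv"
        presence.to_csv(artifacts["hbond_presence"], index=False)
        window = min(cfg.smoothing_window, (len(presence) // 2) * 2 - 1)
        artifacts["hbond_density"] = out / "hbond_density.csv"
        hbond_density(presence, window=max(window, 1)).to_csv(
            artifacts["hbond_density"], index=False)
        artifacts["hbond_occupancy"] = out / "hbond_occupancy.csv"
        hbond_occupancy(presence).to_csv(artifacts["hbond_occupancy"], index=False)
        log.info("hydrogen bonds: %d candidates", presence.shape[1])

        if cfg.rmsd_matrices:
            stage = "RMSD dissimilarity"
            for chain in topo.chains:
                m = rmsd_dissimilarity_matrix(traj, select_chain(topo, chain))
                artifacts[f"rmsd_{chain}"] = out / f"rmsd_{chain}.csv"
                np.savetxt(artifacts[f"rmsd_{chain}"], m, delimiter=",", fmt="%.5f")

        stage = "contact map"
        cmap = sidechain_contact_map(traj, topo, cutoff=cfg.contact_cutoff)
        artifacts["contact_map"] = out / "contact_map.csv"
        cmap.to_csv(artifacts["contact_map"])

        if cfg.classify:
            stage = "conformation classification"
            labels = [
                classify_dimer_conformation(f, topo, contact_cutoff=cfg.contact_cutoff)
                for f in traj.frames
            ]
            artifacts["classification"] = out / "classification.csv"
            pd.DataFrame(
                {"frame": range(traj.n_frames),
                 "time_ps": [f.time for f in traj.frames],
                 "conformation": labels}
            ).to_csv(artifacts["classification"], index=False)

        if cfg.plots:
            stage = "plots"
            _write_plots(matrix, out, artifacts)

        stage = "manifest"
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(json.dumps(
            {
                "dimerpbsa": __version__,
                "versions": _versions(),
                "seed": cfg.seed,
                "config": dataclasses.asdict(cfg),
                "artifacts": {k: str(v) for k, v in artifacts.items()},
            },
            indent=1,
        ))
    except Exception as exc:
        for p in artifacts.values():
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return artifacts


def _versions() -> dict[str, str]:
    import MDAnalysis
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "MDAnalysis": MDAnalysis.__version__,
    }


def _write_plots(matrix: pd.DataFrame, out: Path, artifacts: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    t = matrix["time_ps"] / 1000.0
    for col in ("dE_bind", "dE_MM", "dE_sol"):
        ax.plot(t, matrix[col] - matrix[col].mean(), label=col, lw=0.8)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("mean-centered energy (kcal/mol)")
    ax.legend()
    artifacts["energy_plot"] = out / "binding_energy.png"
    fig.savefig(artifacts["energy_plot"], dpi=120)
    plt.close(fig)
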