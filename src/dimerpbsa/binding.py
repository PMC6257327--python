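"""Per-frame MM-PBSA binding-energy decomposition and trajectory statistics.

The decomposition follows the single-trajectory protocol: monomer energies
are computed on coordinates excised from the complex frame, so the bonded
(internal) contribution cancels identically in the binding difference.

Per frame, 18 components are assembled: E_MM, E_int, E_ele, E_vdw, E_sol for
the complex and for each monomer, plus the differences dE_bind, dE_MM and
dE_sol, with

    dE_bind = E_C - E_A - E_B          (per-frame form of the binding energy)
    dE_bind = dE_MM + dE_sol           (MM / solvation split)

Trajectory averages of the same bookkeeping give the binding free energy
Delta-G_bind = <G_C> - <G_A> - <G_B> = <dE_MM> + <dG_sol>; the configurational
entropy correction -T*Delta-S is estimated separately with the Schlitter
covariance-matrix upper bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    A2_M2, AMU_KG, DEFAULT_TEMPERATURE, E_EULER_SQ, HBAR_SI, K_B, K_B_SI,
)
from .mm_energy import mm_energy
from .model_io import ForceField, Frame, Selection, Topology, Trajectory, select_chain
from .solvation import SolvationConfig, solvation_energy
from .structure import kabsch_superpose

__all__ = [
    "ENERGY_COLUMNS",
    "EnergySummary",
    "EntropyResult",
    "frame_binding_energy",
    "energy_matrix",
    "trajectory_summary",
    "combine_free_energies",
    "combine_mm_solvation",
    "schlitter_entropy",
    "entropy_correction",
]

#: Fixed column order of the per-frame energy matrix (18 components).
ENERGY_COLUMNS = [
    "E_MM_C", "E_int_C", "E_ele_C", "E_vdw_C", "E_sol_C",
    "E_MM_A", "E_int_A", "E_ele_A", "E_vdw_A", "E_sol_A",
    "E_MM_B", "E_int_B", "E_ele_B", "E_vdw_B", "E_sol_B",
    "dE_bind", "dE_MM", "dE_sol",
]


@dataclass(frozen=True)
class EnergySummary:
    """Means and population standard deviations of the free-energy terms."""

    mean: dict
    sd: dict
    n_frames: int
    temperature: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


@dataclass(frozen=True)
class EntropyResult:
    s: float            # kcal/(mol K)
    minus_t_s: float    # kcal/mol
    temperature: float  # K
    n_frames: int


def combine_free_energies(g_complex: float, g_a: float, g_b: float) -> float:
    """Binding free energy from the species means: <G_C> - <G_A> - <G_B>."""
    return g_complex - g_a - g_b


def combine_mm_solvation(de_mm: float, dg_sol: float) -> float:
    """Binding free energy from its MM and solvation parts."""
    return de_mm + dg_sol


def frame_binding_energy(
    frame: Frame,
    selections: tuple[Selection, Selection, Selection],
    ff: ForceField,
    topology: Topology,
    cfg: SolvationConfig = SolvationConfig(),
) -> dict:
    """All 18 binding-energy components of one frame (kcal/mol)."""
    sel_c, sel_a, sel_b = selections
    row: dict[str, float] = {}
    for sel, tag in ((sel_c, "C"), (sel_a, "A"), (sel_b, "B")):
        mm = mm_energy(frame, sel, ff, topology)
        sol = solvation_energy(frame, sel, ff, cfg)
        row[f"E_MM_{tag}"] = mm.e_mm
        row[f"E_int_{tag}"] = mm.e_int
        row[f"E_ele_{tag}"] = mm.e_ele
        row[f"E_vdw_{tag}"] = mm.e_vdw
        row[f"E_sol_{tag}"] = sol
    row["dE_MM"] = row["E_MM_C"] - row["E_MM_A"] - row["E_MM_B"]
    row["dE_sol"] = row["E_sol_C"] - row["E_sol_A"] - row["E_sol_B"]
    row["dE_bind"] = row["dE_MM"] + row["dE_sol"]
    row["time_ps"] = frame.time
    return row


def energy_matrix(
    trajectory: Trajectory,
    ff: ForceField,
    cfg: SolvationConfig = SolvationConfig(),
    progress: bool = False,
) -> pd.DataFrame:
    """Per-frame (n_frames x 18) energy matrix plus a ``time_ps`` column."""
    topo = trajectory.topology
    sels = (
        select_chain(topo, "complex"),
        select_chain(topo, topo.chains[0]),
        select_chain(topo, topo.chains[1]),
    )
    rows = []
    iterator = trajectory.frames
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="energy matrix")
        except ImportError:  # pragma: no cover
            pass
    for f in iterator:
        rows.append(frame_binding_energy(f, sels, ff, topo, cfg))
    return pd.DataFrame(rows, columns=ENERGY_COLUMNS + ["time_ps"])


def trajectory_summary(
    matrix: pd.DataFrame, temperature: float = DEFAULT_TEMPERATURE
) -> EnergySummary:
    """Means and population (ddof=0) standard deviations of the free-energy
    terms: dG_bind, G_C, G_A, G_B, dE_MM and dG_sol."""
    if len(matrix) < 2:
        raise ValueError("summary requires at least 2 frames")
    series = {
        "dG_bind": matrix["dE_bind"],
        "G_C": matrix["E_MM_C"] + matrix["E_sol_C"],
        "G_A": matrix["E_MM_A"] + matrix["E_sol_A"],
        "G_B": matrix["E_MM_B"] + matrix["E_sol_B"],
        "dE_MM": matrix["dE_MM"],
        "dG_sol": matrix["dE_sol"],
    }
    mean = {k: float(v.mean()) for k, v in series.items()}
    sd = {k: float(v.std(ddof=0)) for k, v in series.items()}
    return EnergySummary(mean=mean, sd=sd, n_frames=len(matrix),
                         temperature=temperature)


def schlitter_entropy(
    trajectory: Trajectory,
    selection: Selection,
    masses: np.ndarray | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    fit: bool = True,
) -> EntropyResult:
    """Schlitter quasi-harmonic entropy upper bound (kcal/(mol·K)).

    S = (k_B/2) ln det[ 1 + (k_B T e²/ħ²) M^{1/2} C M^{1/2} ]

    where C is the Cartesian covariance of the selection over the trajectory
    after rigid-body superposition onto the mean structure (disable with
    ``fit=False`` when the input is already an internal-motion ensemble).
    """
    if trajectory.n_frames < 2:
        raise ValueError("entropy estimation requires at least 2 frames")
    idx = selection.atom_indices
    if masses is None:
        masses = trajectory.topology.masses()[idx]
    else:
        masses = np.asarray(masses, dtype=float)
        if masses.size != idx.size:
            raise ValueError("masses length must match the selection size")
    coords = trajectory.coordinates()[:, idx, :].astype(float)
    n_frames, n_atoms = coords.shape[:2]

    if fit and n_atoms >= 3:
        ref = coords[0] - coords[0].mean(axis=0)
        for _ in range(2):  # align to running mean; converges immediately here
            fitted = np.array([kabsch_superpose(c, ref) for c in coords])
            ref = fitted.mean(axis=0)
            ref -= ref.mean(axis=0)
        coords = fitted

    x = coords.reshape(n_frames, 3 * n_atoms)
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / n_frames  # population covariance, Å² amu-less
    if n_frames - 1 < 3 * n_atoms:
        warnings.warn(
            "fewer frames than Cartesian degrees of freedom: covariance is "
            "rank-deficient, using the pseudo-determinant over positive modes",
            stacklevel=2,
        )
    m_sqrt = np.sqrt(np.repeat(masses, 3))
    mcm = cov * np.outer(m_sqrt, m_sqrt)  # amu Å²
    eigvals = np.linalg.eigvalsh((mcm + mcm.T) / 2.0)
    eigvals = np.clip(eigvals, 0.0, None)
    alpha = K_B_SI * temperature * E_EULER_SQ / HBAR_SI ** 2 * AMU_KG * A2_M2
    s = 0.5 * K_B * float(np.log1p(alpha * eigvals).sum())
    return EntropyResult(
        s=s, minus_t_s=-temperature * s, temperature=temperature,
        n_frames=n_frames,
    )


def entropy_correction(
    minus_ts_complex: float, minus_ts_a: float, minus_ts_b: float
) -> float:
    """-T*Delta-S = (-T S_C) - (-T S_A) - (-T S_B), kcal/mol."""
    return minus_ts_complex - minus_ts_a - minus_ts_b
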