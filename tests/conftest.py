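"""Shared fixtures: toy dimer systems and small staged trajectories.

Session-scoped because construction is deterministic and read-only; tests
never mutate fixture objects.
"""

import numpy as np
import pytest

from dimerpbsa.binding import energy_matrix
from dimerpbsa.model_io import Frame
from dimerpbsa.solvation import SolvationConfig
from dimerpbsa.synthetic import (
    PlantedBond,
    StagePlan,
    build_toy_dimer,
    generate_staged_trajectory,
    reference_coordinates,
)

#: Reduced sphere-point count for tests that exercise bookkeeping rather than
#: SASA accuracy (the golden-spiral sampler's accuracy has its own tests).
FAST_SOLVATION = SolvationConfig(n_sphere_points=240)


@pytest.fixture(scope="session")
def toy5():
    """5-residue-per-chain toy dimer: (Topology, ForceField)."""
    return build_toy_dimer(5, seed=1)


@pytest.fixture(scope="session")
def ref_frame(toy5):
    """Reference complex frame at 12 A separation (noise-free)."""
    topo, _ = toy5
    return Frame(coordinates=reference_coordinates(topo, 12.0), time=4.0)


@pytest.fixture(scope="session")
def staged_traj(toy5):
    """120-frame staged trajectory with the default four-stage plan."""
    topo, _ = toy5
    plan = StagePlan.default(n_frames=120, seed=2)
    return generate_staged_trajectory(topo, plan)


@pytest.fixture(scope="session")
def staged_matrix(toy5, staged_traj):
    """Energy matrix of the 120-frame staged trajectory (GB engine)."""
    _, ff = toy5
    return energy_matrix(staged_traj, ff, FAST_SOLVATION)


@pytest.fixture(scope="session")
def planted_traj(toy5):
    """60-frame trajectory with three planted hydrogen bonds.

    One inter-chain bond (always on), one intra-A and one intra-B bond with
    explicit frame schedules.
    """
    topo, _ = toy5
    bonds = (
        PlantedBond(donor_chain="A", donor_residue=3, acceptor_chain="B",
                    acceptor_residue=2, occupancy=1.0),
        PlantedBond(donor_chain="A", donor_residue=1, acceptor_chain="A",
                    acceptor_residue=4, acceptor_atom="O",
                    frames=tuple(range(0, 30))),
        PlantedBond(donor_chain="B", donor_residue=1, acceptor_chain="B",
                    acceptor_residue=4, acceptor_atom="O",
                    frames=tuple(range(15, 60))),
    )
    plan = StagePlan(n_frames=60, stage_separations=(12.0,),
                     contact_schedule=bonds, noise=0.05, seed=5)
    return generate_staged_trajectory(topo, plan)


def stage_recovery_trial(seed: int, n_frames: int = 1000,
                         noise_sd: float = 1.0) -> bool:
    """One synthetic stage-recovery experiment.

    Proxy MM/solvation series are built from the default four-stage
    separation profile plus white noise (MM tracks the profile, solvation
    anti-tracks it), then normalized, smoothed (window 41) and segmented
    (extremum window 31).  Success: every planted boundary is recovered
    within half the smoothing window and no spurious boundary appears.
    """
    from dimerpbsa.synthetic import StagePlan
    from dimerpbsa.timeseries import (
        moving_average, normalize_series, segment_stages,
    )

    smoothing, extremum_window = 41, 31
    plan = StagePlan.default(n_frames=n_frames, seed=0)
    profile = plan.separation_profile()
    rng = np.random.default_rng(10000 + seed)
    de_mm = profile + rng.normal(0.0, noise_sd, n_frames)
    de_sol = -profile + rng.normal(0.0, noise_sd, n_frames)
    sm_mm = moving_average(normalize_series(de_mm), smoothing)
    sm_sol = moving_average(normalize_series(de_sol), smoothing)
    sb = segment_stages(sm_mm, sm_sol, window=extremum_window)
    tol = smoothing // 2
    if len(sb.boundaries) != len(plan.boundaries):
        return False
    return all(abs(f - b) <= tol
               for f, b in zip(sb.boundaries, plan.boundaries))


def rigid_transform(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a random rotation + translation (deterministic per seed)."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=seed)
    return rot.apply(coords) + rng.normal(0.0, 20.0, 3)
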