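"""Structural analyses: Kabsch RMSD, hydrogen bonds, presence/density/
occupancy statistics, contact maps and dimer-conformation classification."""

import math

import numpy as np
import pytest

from dimerpbsa.model_io import Frame, Selection, Trajectory, select_chain
from dimerpbsa.structure import (
    CONFORMATION_CLASSES,
    classify_dimer_conformation,
    detect_hbonds,
    hbond_density,
    hbond_occupancy,
    hbond_presence_matrix,
    kabsch_rmsd,
    rmsd_dissimilarity_matrix,
    sidechain_contact_map,
)
from dimerpbsa.synthetic import build_toy_dimer, reference_coordinates

from conftest import rigid_transform


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

class TestKabschRmsd:
    def test_identical_frames_zero(self, toy5, ref_frame):
        topo, _ = toy5
        sel = select_chain(topo, "complex")
        assert kabsch_rmsd(ref_frame, ref_frame, sel) == pytest.approx(
            0.0, abs=1e-12)

    def test_rigid_copy_zero(self, toy5, ref_frame):
        topo, _ = toy5
        sel = select_chain(topo, "complex")
        moved = Frame(rigid_transform(ref_frame.coordinates, seed=4),
                      time=8.0)
        assert kabsch_rmsd(ref_frame, moved, sel) <= 1e-8

    def test_against_mdanalysis_oracle(self, toy5, ref_frame, staged_traj):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        topo, _ = toy5
        sel = select_chain(topo, "complex")
        for k in (0, 33, 77):
            frame = staged_traj.frames[k]
            ours = kabsch_rmsd(ref_frame, frame, sel)
            theirs = mda_rmsd(ref_frame.coordinates, frame.coordinates,
                              center=True, superposition=True)
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_against_numerical_minimization(self):
        # independent oracle: minimize RMSD over rotation vectors numerically
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        a = rng.normal(0, 2.0, (6, 3))
        b = rng.normal(0, 2.0, (6, 3))
        fa = Frame(a, time=1.0)
        fb = Frame(b, time=1.0)
        sel = Selection("complex", np.arange(6))
        ours = kabsch_rmsd(fa, fb, sel)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def cost(rv):
            rot = Rotation.from_rotvec(rv)
            return float(np.sqrt(((rot.apply(bc) - ac) ** 2).sum(1).mean()))

        best = min(
            minimize(cost, rv0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14,
                              "maxiter": 20000}).fun
            for rv0 in ([0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5],
                        [2.0, 2.0, 0.5])
        )
        assert ours == pytest.approx(best, abs=1e-6)

    def test_too_few_atoms_rejected(self, ref_frame):
        sel = Selection("tiny", np.array([0, 1]))
        with pytest.raises(ValueError):
            kabsch_rmsd(ref_frame, ref_frame, sel)


class TestDissimilarityMatrix:
    def test_symmetric_zero_diagonal(self, toy5, staged_traj):
        topo, _ = toy5
        short = Trajectory(topology=topo, frames=staged_traj.frames[:8],
                           dt=staged_traj.dt)
        m = rmsd_dissimilarity_matrix(short, select_chain(topo, "A"))
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
        assert np.all(m >= 0.0)

    def test_static_trajectory_all_zero(self, toy5, ref_frame):
        topo, _ = toy5
        frames = tuple(Frame(ref_frame.coordinates, time=4.0 * (k + 1))
                       for k in range(4))
        traj = Trajectory(topology=topo, frames=frames, dt=4.0)
        m = rmsd_dissimilarity_matrix(traj, select_chain(topo, "complex"))
        np.testing.assert_allclose(m, 0.0, atol=1e-10)

    def test_entries_match_pairwise_calls(self, toy5, staged_traj):
        topo, _ = toy5
        short = Trajectory(topology=topo, frames=staged_traj.frames[:6],
                           dt=staged_traj.dt)
        sel = select_chain(topo, "B")
        m = rmsd_dissimilarity_matrix(short, sel)
        for i, j in ((0, 3), (1, 5), (2, 4)):
            assert m[i, j] == pytest.approx(
                kabsch_rmsd(short.frames[i], short.frames[j], sel), abs=1e-10)

    def test_global_rigid_motion_leaves_matrix_unchanged(self, toy5,
                                                         staged_traj):
        topo, _ = toy5
        sel = select_chain(topo, "A")
        frames = staged_traj.frames[:5]
        short = Trajectory(topology=topo, frames=frames, dt=staged_traj.dt)
        moved = Trajectory(
            topology=topo,
            frames=tuple(
                Frame(rigid_transform(f.coordinates, seed=50 + k),
                      time=f.time)
                for k, f in enumerate(frames)
            ),
            dt=staged_traj.dt,
        )
        m0 = rmsd_dissimilarity_matrix(short, sel)
        m1 = rmsd_dissimilarity_matrix(moved, sel)
        np.testing.assert_allclose(m1, m0, atol=1e-8)


# ---------------------------------------------------------------------------
# hydrogen-bond detection
# ---------------------------------------------------------------------------

def _planted_geometry(topo, donor_res, acceptor_chain, acceptor_res,
                      acceptor_name, angle_deg=180.0):
    """Reference coordinates with one acceptor moved to a chosen D-H-A angle
    at 2.9 A donor-acceptor distance (donor: backbone N-H of chain A)."""
    coords = reference_coordinates(topo, 12.0).copy()
    don = next(a.serial for a in topo.atoms
               if a.chain_id == "A" and a.residue_index == donor_res
               and a.name == "N")
    hyd = next(a.serial for a in topo.atoms
               if a.chain_id == "A" and a.residue_index == donor_res
               and a.name == "H")
    acc = next(a.serial for a in topo.atoms
               if a.chain_id == acceptor_chain
               and a.residue_index == acceptor_res
               and a.name == acceptor_name)
    nh = coords[hyd] - coords[don]
    nh /= np.linalg.norm(nh)
    perp = np.cross(nh, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    # place the acceptor so the D-H-A angle equals angle_deg exactly
    theta = math.radians(180.0 - angle_deg)
    direction = math.cos(theta) * nh + math.sin(theta) * perp
    d_h = float(np.linalg.norm(coords[hyd] - coords[don]))
    # distance from H chosen so |D-A| = 2.9
    # law of cosines: d_DA^2 = d_DH^2 + d_HA^2 - 2 d_DH d_HA cos(angle)
    cos_a = math.cos(math.radians(angle_deg))
    d_ha = d_h * cos_a + math.sqrt((d_h * cos_a) ** 2 + 2.9 ** 2 - d_h ** 2)
    coords[acc] = coords[hyd] + d_ha * direction
    return coords, (don, hyd, acc)


class TestDetectHbonds:
    def test_ideal_geometry_detected(self, toy5):
        topo, _ = toy5
        coords, (don, hyd, acc) = _planted_geometry(topo, 3, "B", 2, "OD")
        found = detect_hbonds(Frame(coords, time=1.0), topo)
        assert any(r.donor == don and r.acceptor == acc for r in found)

    def test_bent_geometry_rejected(self, toy5):
        topo, _ = toy5
        coords, (don, hyd, acc) = _planted_geometry(topo, 3, "B", 2, "OD",
                                                    angle_deg=100.0)
        found = detect_hbonds(Frame(coords, time=1.0), topo)
        assert not any(r.donor == don and r.acceptor == acc for r in found)

    def test_distance_cutoff(self, toy5):
        topo, _ = toy5
        coords, (don, hyd, acc) = _planted_geometry(topo, 3, "B", 2, "OD")
        frame = Frame(coords, time=1.0)
        assert any(r.acceptor == acc
                   for r in detect_hbonds(frame, topo, dist_cutoff=3.0))
        assert not any(r.acceptor == acc
                       for r in detect_hbonds(frame, topo, dist_cutoff=2.5))

    def test_nearby_covalent_acceptor_skipped(self, toy5):
        # the donor's own CA (2 bonds away) can never be an acceptor;
        # verify no detected bond ever links atoms within two covalent bonds
        topo, _ = toy5
        coords, _ = _planted_geometry(topo, 3, "B", 2, "OD")
        adj = {}
        for i, j in topo.bonds:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        for r in detect_hbonds(Frame(coords, time=1.0), topo):
            near = set(adj.get(r.donor, ())) | {r.donor}
            near |= {k for j in list(near) for k in adj.get(j, ())}
            assert r.acceptor not in near

    def test_categories(self, planted_traj, toy5):
        topo, _ = toy5
        cats = set()
        for f in planted_traj.frames:
            cats |= {r.category for r in detect_hbonds(f, topo)}
        assert {"inter", "intra_A", "intra_B"} <= cats


class TestPresenceMatrix:
    def test_row_sums_match_per_frame_detection(self, planted_traj, toy5):
        topo, _ = toy5
        presence = hbond_presence_matrix(planted_traj)
        counts = [len(detect_hbonds(f, topo)) for f in planted_traj.frames]
        np.testing.assert_array_equal(presence.sum(axis=1).to_numpy(), counts)

    def test_persistent_bond_all_ones(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        col = presence["A:ALA3:N->B:ASP2:OD"]
        assert col.sum() == len(presence)

    def test_planted_schedules_recovered_exactly(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        intra_a = presence["A:ALA1:N->A:LYS4:O"].to_numpy()
        intra_b = presence["B:ALA1:N->B:LYS4:O"].to_numpy()
        np.testing.assert_array_equal(np.nonzero(intra_a)[0],
                                      np.arange(0, 30))
        np.testing.assert_array_equal(np.nonzero(intra_b)[0],
                                      np.arange(15, 60))

    def test_category_attribute(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        cats = presence.attrs["categories"]
        assert cats["A:ALA3:N->B:ASP2:OD"] == "inter"
        assert cats["A:ALA1:N->A:LYS4:O"] == "intra_A"
        assert cats["B:ALA1:N->B:LYS4:O"] == "intra_B"


class TestDensityOccupancy:
    def test_density_partition(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        dens = hbond_density(presence, window=11)
        np.testing.assert_allclose(
            dens["total"],
            dens["inter"] + dens["intra_A"] + dens["intra_B"], atol=1e-10)

    def test_constant_presence_constant_density(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        dens = hbond_density(presence[["A:ALA3:N->B:ASP2:OD"]].copy(),
                             window=7)
        # single always-on bond, but the sliced frame loses attrs ->
        # categories default empty; total still constant 1
        np.testing.assert_allclose(dens["total"], 1.0, atol=1e-12)

    def test_window_longer_than_trajectory_rejected(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        with pytest.raises(ValueError):
            hbond_density(presence, window=2 * len(presence) + 1)

    def test_occupancy_fraction(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        occ = hbond_occupancy(presence).set_index("bond")
        assert occ.loc["A:ALA3:N->B:ASP2:OD", "occupancy_percent"] == \
            pytest.approx(100.0, abs=1e-12)
        assert occ.loc["A:ALA1:N->A:LYS4:O", "occupancy_percent"] == \
            pytest.approx(100.0 * 30 / 60, abs=1e-12)
        assert occ.loc["B:ALA1:N->B:LYS4:O", "occupancy_percent"] == \
            pytest.approx(100.0 * 45 / 60, abs=1e-12)

    def test_occupancy_sorted_descending(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        occ = hbond_occupancy(presence)["occupancy_percent"].to_numpy()
        assert np.all(np.diff(occ) <= 1e-12)

    def test_top_n(self, planted_traj):
        presence = hbond_presence_matrix(planted_traj)
        assert len(hbond_occupancy(presence, top_n=2)) == 2

    def test_four_of_ten_frames_forty_percent(self, planted_traj):
        import pandas as pd

        presence = pd.DataFrame({"b": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]})
        occ = hbond_occupancy(presence)
        assert occ["occupancy_percent"].iloc[0] == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def _contact_frame(topo, separation):
    """Toy-dimer frame with A and B side-chain centroids of residue pairs at
    a controlled distance: simply the reference frame at ``separation``."""
    return Frame(reference_coordinates(topo, separation), time=1.0)


class TestContactMap:
    def test_cutoff_boundary(self, toy5):
        topo, _ = toy5
        # in the reference geometry the closest cross-chain side-chain pair
        # (A:1, B:4) sits at sqrt(1.2^2 + (sep-4)^2): 6.41 A at sep 10.3,
        # 6.61 A at sep 10.5, bracketing the 6.5 A cutoff
        m_in = sidechain_contact_map(_contact_frame(topo, 10.3), topo)
        m_out = sidechain_contact_map(_contact_frame(topo, 10.5), topo)
        assert m_in.loc["A:1", "B:4"] == 1.0
        assert m_out.loc["A:1", "B:4"] == 0.0

    def test_hand_computed_single_frame(self, toy5):
        topo, _ = toy5
        frame = _contact_frame(topo, 10.3)
        m = sidechain_contact_map(frame, topo)
        # reproduce by hand from side-chain atom positions
        side = {}
        for a in topo.atoms:
            if a.name in ("CB", "OD", "NZ"):
                side[(a.chain_id, a.residue_index)] = \
                    frame.coordinates[a.serial]
        for (c1, r1), p1 in side.items():
            for (c2, r2), p2 in side.items():
                if (c1, r1) == (c2, r2):
                    continue
                expected = 1.0 if np.linalg.norm(p1 - p2) < 6.5 else 0.0
                assert m.loc[f"{c1}:{r1}", f"{c2}:{r2}"] == expected

    def test_symmetric_zero_diagonal(self, toy5):
        topo, _ = toy5
        m = sidechain_contact_map(_contact_frame(topo, 9.0), topo)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
        np.testing.assert_allclose(np.diag(m.to_numpy()), 0.0)

    def test_trajectory_fraction(self, toy5):
        topo, _ = toy5
        f1 = Frame(reference_coordinates(topo, 10.3), time=1.0)
        f2 = Frame(reference_coordinates(topo, 20.0), time=2.0)
        traj = Trajectory(topology=topo, frames=(f1, f2), dt=1.0)
        m = sidechain_contact_map(traj, topo)
        assert m.loc["A:1", "B:4"] == pytest.approx(0.5)

    def test_custom_cutoff(self, toy5):
        topo, _ = toy5
        frame = _contact_frame(topo, 10.5)
        strict = sidechain_contact_map(frame, topo, cutoff=6.5)
        loose = sidechain_contact_map(frame, topo, cutoff=7.0)
        assert strict.loc["A:1", "B:4"] == 0.0
        assert loose.loc["A:1", "B:4"] == 1.0


# ---------------------------------------------------------------------------
# conformation classification
# ---------------------------------------------------------------------------

_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "H": np.array([0.0, 1.0, 0.0]),
    "CA": np.array([1.3, -0.6, 0.0]),
    "C": np.array([2.4, 0.2, 0.0]),
    "O": np.array([2.4, -1.03, 0.0]),
    "SIDE": np.array([1.3, -0.6, 2.0]),
}

# hairpin base trace: 4-residue strand, apex, 3-residue return strand
_HAIRPIN = np.array([
    [0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 0.0, 0.0], [11.4, 0.0, 0.0],
    [13.3, 2.4, 0.0],
    [11.4, 4.8, 0.0], [7.6, 4.8, 0.0], [3.8, 4.8, 0.0],
])

# mirror hairpin running the other way along x, stacked above in y/z
_HAIRPIN_B = np.array([
    [13.3, 12.0, 4.0], [9.5, 12.0, 4.0], [5.7, 12.0, 4.0], [1.9, 12.0, 4.0],
    [0.0, 9.6, 4.0],
    [1.9, 7.2, 4.0], [5.7, 7.2, 4.0], [9.5, 7.2, 4.0],
])

# straight 8-residue line along y at x=4, z=4 (wraps the hairpin opening)
_LINE = np.column_stack([
    np.full(8, 4.0), np.linspace(-6.0, 16.0, 8), np.full(8, 4.0),
])

# straight line far away, parallel to the x axis (no contacts, no wrap)
_FAR_LINE = np.column_stack([
    np.linspace(0.0, 26.6, 8), np.full(8, 60.0), np.full(8, 4.0),
])


def _frame_from_bases(topo, bases_a, bases_b):
    coords = np.zeros((topo.n_atoms, 3))
    for a in topo.atoms:
        base = (bases_a if a.chain_id == "A" else bases_b)[a.residue_index - 1]
        off = _OFFSETS.get(a.name, _OFFSETS["SIDE"])
        coords[a.serial] = base + off
    return Frame(coords, time=1.0)


@pytest.fixture(scope="module")
def toy8():
    topo, _ = build_toy_dimer(8, seed=0)
    return topo


class TestClassification:
    def test_class_list(self):
        assert len(CONFORMATION_CLASSES) == 11
        assert "unclassified" in CONFORMATION_CLASSES

    def test_two_hairpins_cc_antiparallel(self, toy8):
        frame = _frame_from_bases(toy8, _HAIRPIN, _HAIRPIN_B)
        assert classify_dimer_conformation(frame, toy8) == "CC-antiparallel"

    def test_chain_swap_invariance(self, toy8):
        frame = _frame_from_bases(toy8, _HAIRPIN_B, _HAIRPIN)
        assert classify_dimer_conformation(frame, toy8) == "CC-antiparallel"

    def test_one_hairpin_wrapped_is_nested(self, toy8):
        frame = _frame_from_bases(toy8, _HAIRPIN, _LINE)
        assert classify_dimer_conformation(frame, toy8) == "nested-parallel"

    def test_one_hairpin_unwrapped_unclassified(self, toy8):
        frame = _frame_from_bases(toy8, _HAIRPIN, _FAR_LINE)
        assert classify_dimer_conformation(frame, toy8) == "unclassified"

    def test_two_extended_chains_unclassified(self, toy8):
        line_a = np.column_stack([
            np.linspace(0.0, 26.6, 8), np.zeros(8), np.zeros(8)])
        line_b = np.column_stack([
            np.linspace(0.0, 26.6, 8), np.full(8, 5.0), np.full(8, 4.0)])
        frame = _frame_from_bases(toy8, line_a, line_b)
        assert classify_dimer_conformation(frame, toy8) == "unclassified"

    def test_label_always_in_taxonomy(self, toy8):
        for sep in (8.0, 12.0, 20.0):
            frame = Frame(reference_coordinates(toy8, sep), time=1.0)
            label = classify_dimer_conformation(frame, toy8)
            assert label in CONFORMATION_CLASSES

    def test_too_few_residues_rejected(self, toy5, ref_frame):
        topo, _ = toy5
        with pytest.raises(ValueError, match="6 residues"):
            classify_dimer_conformation(ref_frame, topo)
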