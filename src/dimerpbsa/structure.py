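"""Structural analyses of dimer trajectories.

Pairwise Kabsch RMSD dissimilarity matrices, geometric hydrogen-bond
detection with inter/intra classification, bond presence matrices, density
and occupancy statistics, side-chain contact maps at a 6.5 Å centroid
cutoff, and the 10-class dimer-conformation taxonomy (NN/NC/CC x
parallel/antiparallel for two-hairpin dimers, nested/antinested variants
when only one monomer forms a hairpin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model_io import Frame, Selection, Topology, Trajectory

__all__ = [
    "HBondRecord",
    "CONFORMATION_CLASSES",
    "kabsch_superpose",
    "kabsch_rmsd",
    "rmsd_dissimilarity_matrix",
    "detect_hbonds",
    "hbond_presence_matrix",
    "hbond_density",
    "hbond_occupancy",
    "sidechain_contact_map",
    "classify_dimer_conformation",
]

CONFORMATION_CLASSES = (
    "NN-parallel", "NC-parallel", "CC-parallel",
    "NN-antiparallel", "NC-antiparallel", "CC-antiparallel",
    "nested-parallel", "nested-antiparallel",
    "antinested-parallel", "antinested-antiparallel",
    "unclassified",
)


@dataclass(frozen=True, order=True)
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    category: str  # "inter", "intra_A", "intra_B"


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``reference`` (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + reference.mean(axis=0)


def kabsch_rmsd(frame_a: Frame, frame_b: Frame, selection: Selection) -> float:
    """Minimal RMSD (Å) over rigid superposition of the selected atoms."""
    idx = selection.atom_indices
    if idx.size < 3:
        raise ValueError("RMSD superposition requires at least 3 atoms")
    a = frame_a.coordinates[idx]
    b = frame_b.coordinates[idx]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    return _aligned_rmsd(ac, bc)


def _aligned_rmsd(ac: np.ndarray, bc: np.ndarray) -> float:
    """RMSD between centered coordinate sets after optimal rotation.

    The residual is evaluated on the explicitly rotated coordinates rather
    than via the closed-form trace expression, which loses accuracy to
    cancellation when the two sets are near-identical.
    """
    rot, _ = Rotation.align_vectors(ac, bc)
    diff = rot.apply(bc) - ac
    return float(math.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_dissimilarity_matrix(
    trajectory: Trajectory, selection: Selection
) -> np.ndarray:
    """Symmetric (n_frames, n_frames) matrix of pairwise Kabsch RMSDs."""
    if trajectory.n_frames < 2:
        raise ValueError("dissimilarity matrix needs at least 2 frames")
    idx = selection.atom_indices
    if idx.size < 3:
        raise ValueError("RMSD superposition requires at least 3 atoms")
    coords = [f.coordinates[idx] for f in trajectory.frames]
    centered = [c - c.mean(axis=0) for c in coords]
    n = len(centered)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _aligned_rmsd(centered[i], centered[j])
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _donor_h_pairs(topology: Topology) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs: N/O heavy atoms with a covalently bound H."""
    pairs = []
    for i, j in sorted(topology.bonds):
        ai, aj = topology.atoms[i], topology.atoms[j]
        if ai.element in ("N", "O") and aj.element == "H":
            pairs.append((i, j))
        elif aj.element in ("N", "O") and ai.element == "H":
            pairs.append((j, i))
    return sorted(pairs)


def _acceptors(topology: Topology) -> np.ndarray:
    return np.array(
        [a.serial for a in topology.atoms if a.element in ("N", "O")], dtype=int
    )


def _bond_neighbors(topology: Topology) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for i, j in topology.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    return adj


def _category(topology: Topology, donor: int, acceptor: int) -> str:
    ca = topology.atoms[donor].chain_id
    cb = topology.atoms[acceptor].chain_id
    if ca != cb:
        return "inter"
    return f"intra_{ca}"


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> set[HBondRecord]:
    """Geometric hydrogen bonds in one frame.

    A bond is recorded when the donor–acceptor distance is at most
    ``dist_cutoff`` (Å) and the donor–H–acceptor angle (vertex at H) is at
    least ``angle_cutoff`` (degrees).  Acceptors within two covalent bonds of
    the donor are skipped.
    """
    x = frame.coordinates
    adj = _bond_neighbors(topology)
    acceptors = _acceptors(topology)
    cos_min = math.cos(math.radians(angle_cutoff))
    records: set[HBondRecord] = set()
    for donor, hydrogen in _donor_h_pairs(topology):
        near = set(adj.get(donor, ()))
        near |= {k for j in near for k in adj.get(j, ())}
        near.add(donor)
        dvec = x[acceptors] - x[donor]
        dist = np.linalg.norm(dvec, axis=1)
        for acc, d in zip(acceptors, dist):
            if int(acc) in near or d > dist_cutoff:
                continue
            v1 = x[donor] - x[hydrogen]
            v2 = x[acc] - x[hydrogen]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
            if float(np.dot(v1, v2)) / denom <= cos_min:
                records.add(
                    HBondRecord(
                        donor=int(donor), hydrogen=int(hydrogen),
                        acceptor=int(acc),
                        category=_category(topology, int(donor), int(acc)),
                    )
                )
    return records


def hbond_label(topology: Topology, rec: HBondRecord) -> str:
    d, a = topology.atoms[rec.donor], topology.atoms[rec.acceptor]
    return (
        f"{d.chain_id}:{d.residue_name}{d.residue_index}:{d.name}"
        f"->{a.chain_id}:{a.residue_name}{a.residue_index}:{a.name}"
    )


def hbond_presence_matrix(
    trajectory: Trajectory,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> pd.DataFrame:
    """Binary (n_frames x n_bonds) presence matrix, no occupancy threshold.

    Candidate bonds are all donor/H/acceptor triples observed in at least one
    frame.  Columns are labelled ``chain:RESi:name->chain:RESj:name`` and
    carry the inter/intra category in ``df.attrs["categories"]``.
    """
    topo = trajectory.topology
    per_frame = [
        detect_hbonds(f, topo, dist_cutoff, angle_cutoff) for f in trajectory.frames
    ]
    candidates = sorted(set().union(*per_frame)) if per_frame else []
    labels = [hbond_label(topo, r) for r in candidates]
    data = np.zeros((trajectory.n_frames, len(candidates)), dtype=int)
    pos = {r: k for k, r in enumerate(candidates)}
    for fi, found in enumerate(per_frame):
        for r in found:
            data[fi, pos[r]] = 1
    df = pd.DataFrame(data, columns=labels)
    df.attrs["categories"] = {
        lab: rec.category for lab, rec in zip(labels, candidates)
    }
    df.attrs["records"] = list(candidates)
    return df


def hbond_density(presence: pd.DataFrame, window: int = 101) -> pd.DataFrame:
    """Moving-average hydrogen-bond count per category along the trajectory.

    Returns a DataFrame with columns ``inter``, ``intra_A``, ``intra_B`` and
    ``total`` (per-frame smoothed counts).
    """
    from .timeseries import moving_average

    if window > len(presence):
        raise ValueError("smoothing window longer than the trajectory")
    cats = presence.attrs.get("categories", {})
    out = {}
    for cat in ("inter", "intra_A", "intra_B"):
        cols = [c for c in presence.columns if cats.get(c) == cat]
        counts = presence[cols].sum(axis=1).to_numpy(dtype=float)
        out[cat] = moving_average(counts, window)
    out["total"] = moving_average(
        presence.sum(axis=1).to_numpy(dtype=float), window
    )
    return pd.DataFrame(out)


def hbond_occupancy(presence: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Occupation table: bond label, category, % of frames present.

    Sorted by descending occupancy; ties keep column order.
    """
    cats = presence.attrs.get("categories", {})
    occ = 100.0 * presence.mean(axis=0)
    table = pd.DataFrame(
        {
            "bond": presence.columns,
            "category": [cats.get(c, "") for c in presence.columns],
            "occupancy_percent": occ.to_numpy(),
        }
    )
    table = table.sort_values(
        "occupancy_percent", ascending=False, kind="stable"
    ).reset_index(drop=True)
    if top_n is not None:
        table = table.head(top_n)
    return table


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

_SIDECHAIN_NAMES = {"CB", "OD", "NZ"}


def _residue_keys(topology: Topology) -> list[tuple[str, int]]:
    return list(dict.fromkeys((a.chain_id, a.residue_index) for a in topology.atoms))


def _sidechain_centers(frame: Frame, topology: Topology) -> np.ndarray:
    """Geometric center of each residue's side chain (CA fallback)."""
    keys = _residue_keys(topology)
    pos = {k: [] for k in keys}
    ca = {}
    for a in topology.atoms:
        key = (a.chain_id, a.residue_index)
        if a.name in _SIDECHAIN_NAMES:
            pos[key].append(frame.coordinates[a.serial])
        if a.name == "CA":
            ca[key] = frame.coordinates[a.serial]
    centers = []
    for key in keys:
        if pos[key]:
            centers.append(np.mean(pos[key], axis=0))
        else:
            centers.append(ca[key])
    return np.array(centers)


def sidechain_contact_map(
    source: Frame | Trajectory,
    topology: Topology,
    cutoff: float = 6.5,
) -> pd.DataFrame:
    """Residue-by-residue side-chain contact map.

    For a single frame the entries are binary (centroid distance < cutoff);
    for a trajectory they are the fraction of frames in contact.  Row/column
    labels are ``chain:resid``.
    """
    keys = _residue_keys(topology)
    labels = [f"{c}:{r}" for c, r in keys]
    frames = source.frames if isinstance(source, Trajectory) else [source]
    acc = np.zeros((len(keys), len(keys)))
    for f in frames:
        centers = _sidechain_centers(f, topology)
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        acc += (d < cutoff).astype(float)
    acc /= len(frames)
    np.fill_diagonal(acc, 0.0)
    if not isinstance(source, Trajectory):
        acc = acc.astype(int).astype(float)
    return pd.DataFrame(acc, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# dimer-conformation classification
# ---------------------------------------------------------------------------

def _ca_trace(frame: Frame, topology: Topology, chain: str) -> np.ndarray:
    idx = [a.serial for a in topology.atoms if a.chain_id == chain and a.name == "CA"]
    return frame.coordinates[idx]


def _find_hairpin(
    ca: np.ndarray, turn_window: int = 2, turn_cos_max: float = -0.3,
    extension_min: float = 0.8, min_strand: int = 2,
) -> int | None:
    """Index of the turn residue if the CA trace forms a hairpin, else None.

    A hairpin is a local direction reversal (cosine between the incoming and
    outgoing ``turn_window``-residue direction vectors below ``turn_cos_max``)
    flanked by two extended strands (end-to-end length over contour length at
    least ``extension_min``).
    """
    n = len(ca)
    k = turn_window
    best, best_cos = None, turn_cos_max
    for i in range(k, n - k):
        v1 = ca[i] - ca[i - k]
        v2 = ca[i + k] - ca[i]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        c = float(np.dot(v1, v2) / denom)
        if c < best_cos:
            best, best_cos = i, c
    if best is None:
        return None
    for lo, hi in ((0, best), (best, n - 1)):
        if hi - lo < min_strand:
            return None
        contour = sum(
            np.linalg.norm(ca[m + 1] - ca[m]) for m in range(lo, hi)
        )
        ee = np.linalg.norm(ca[hi] - ca[lo])
        if contour == 0 or ee / contour < extension_min:
            return None
    return best


def _strand_contacts(
    frame: Frame, topology: Topology, chain: str, turn: int, cutoff: float
) -> tuple[int, int]:
    """Inter-chain side-chain contact counts of the (N flank, C flank)."""
    keys = _residue_keys(topology)
    centers = _sidechain_centers(frame, topology)
    chain_rows = [k for k, key in enumerate(keys) if key[0] == chain]
    other_rows = [k for k, key in enumerate(keys) if key[0] != chain]
    d = np.linalg.norm(
        centers[chain_rows][:, None, :] - centers[other_rows][None, :, :], axis=-1
    )
    contacts = (d < cutoff).sum(axis=1)
    return int(contacts[: turn + 1].sum()), int(contacts[turn:].sum())


def classify_dimer_conformation(
    frame: Frame,
    topology: Topology,
    contact_cutoff: float = 6.5,
    turn_window: int = 2,
    turn_cos_max: float = -0.3,
    extension_min: float = 0.8,
    wrap_angle_min: float = 120.0,
) -> str:
    """One of the ten dimer conformation classes, or ``"unclassified"``.

    Two hairpins: the interface strand of each monomer (more inter-chain
    side-chain contacts) is labelled N or C by the terminus it contains,
    giving NN/NC/CC; orientation is parallel when the two interface strands'
    N-to-C end-to-end vectors have a positive dot product.  One hairpin: if
    the other chain's CA span wraps the hairpin centroid (its termini subtend
    at least ``wrap_angle_min`` degrees), the dimer is nested when the outer
    termini lie on the open side of the hairpin and antinested otherwise.
    """
    chains = topology.chains
    if len(chains) != 2:
        raise ValueError("classification requires exactly two chains")
    traces = {c: _ca_trace(frame, topology, c) for c in chains}
    for c in chains:
        if len(traces[c]) < 6:
            raise ValueError("classification requires at least 6 residues per chain")
    turns = {
        c: _find_hairpin(traces[c], turn_window, turn_cos_max, extension_min)
        for c in chains
    }
    with_turn = [c for c in chains if turns[c] is not None]

    if len(with_turn) == 2:
        letters, vectors = [], []
        for c in chains:
            ca = traces[c]
            t = turns[c]
            n_ct, c_ct = _strand_contacts(frame, topology, c, t, contact_cutoff)
            if n_ct >= c_ct:
                letters.append("N")
                vectors.append(ca[t] - ca[0])
            else:
                letters.append("C")
                vectors.append(ca[-1] - ca[t])
        pair = "".join(sorted(letters))
        orient = "parallel" if float(np.dot(vectors[0], vectors[1])) > 0 else "antiparallel"
        return f"{pair}-{orient}"

    if len(with_turn) == 1:
        inner = with_turn[0]
        outer = chains[0] if chains[1] == inner else chains[1]
        ca_in, ca_out = traces[inner], traces[outer]
        t = turns[inner]
        centroid = ca_in.mean(axis=0)
        u = ca_out[0] - centroid
        v = ca_out[-1] - centroid
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom == 0:
            return "unclassified"
        angle = math.degrees(math.acos(float(np.clip(np.dot(u, v) / denom, -1, 1))))
        if angle < wrap_angle_min:
            return "unclassified"
        # open side of the hairpin: from the turn towards the strand termini
        opening = 0.5 * (ca_in[0] + ca_in[-1]) - ca_in[t]
        outer_mid = 0.5 * (ca_out[0] + ca_out[-1])
        nested = float(np.dot(outer_mid - centroid, opening)) > 0
        n_ct, c_ct = _strand_contacts(frame, topology, inner, t, contact_cutoff)
        inner_vec = (ca_in[t] - ca_in[0]) if n_ct >= c_ct else (ca_in[-1] - ca_in[t])
        outer_vec = ca_out[-1] - ca_out[0]
        orient = "parallel" if float(np.dot(inner_vec, outer_vec)) > 0 else "antiparallel"
        return f"{'nested' if nested else 'antinested'}-{orient}"

    return "unclassified"
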