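"""Gas-phase molecular-mechanics energies: E_MM = E_int + E_ele + E_vdw.

Amber functional forms throughout: harmonic bonds/angles without the 1/2
prefactor, periodic dihedrals (V_n/2)(1 + cos(n*phi - gamma)), Coulomb with
k_e = 332.0636 kcal·Å/(mol·e²), 12-6 Lennard-Jones in r_min/epsilon form with
Lorentz–Berthelot combining.  1-2 and 1-3 pairs are excluded, 1-4 pairs are
scaled by 1/scee (electrostatics) and 1/scnb (LJ).  No distance cutoff is
applied: these are end-state analysis energies, not dynamics forces.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import K_E
from .model_io import ForceField, Frame, Selection, Topology

__all__ = [
    "MMEnergyBreakdown",
    "build_exclusions",
    "bonded_energy",
    "coulomb_energy",
    "lennard_jones_energy",
    "mm_energy",
    "pair_interaction_energy",
]

_MIN_DISTANCE = 0.1  # Å; closer pairs are treated as overlapping atoms


@dataclass(frozen=True)
class MMEnergyBreakdown:
    e_int: float
    e_ele: float
    e_vdw: float

    @property
    def e_mm(self) -> float:
        return self.e_int + self.e_ele + self.e_vdw


def build_exclusions(
    topology: Topology,
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """(excluded 1-2/1-3 pairs, scaled 1-4 pairs), both as sorted index pairs.

    Pairs that are simultaneously 1-4 and 1-2/1-3 (rings) stay excluded.
    """
    adj: dict[int, set[int]] = {}
    for i, j in topology.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excluded: set[tuple[int, int]] = set()
    one_four: set[tuple[int, int]] = set()
    for i in adj:
        for j in adj[i]:
            if i < j:
                excluded.add((i, j))
            for k in adj[j]:
                if k != i and i < k:
                    excluded.add((i, k))
    for i in adj:
        for j in adj[i]:
            for k in adj[j]:
                if k == i:
                    continue
                for l in adj[k]:
                    if l not in (i, j) and i < l:
                        one_four.add((i, l))
    one_four -= excluded
    return frozenset(excluded), frozenset(one_four)


@lru_cache(maxsize=16)
def _cached_exclusions(topology: Topology):
    return build_exclusions(topology)


def _pair_masks(selection: Selection, topology: Topology, n_sel: int):
    """Boolean (n_sel, n_sel) masks for excluded and 1-4 pairs inside a selection."""
    excluded, one_four = _cached_exclusions(topology)
    pos = {int(a): k for k, a in enumerate(selection.atom_indices)}
    excl = np.zeros((n_sel, n_sel), dtype=bool)
    scaled = np.zeros((n_sel, n_sel), dtype=bool)
    for i, j in excluded:
        if i in pos and j in pos:
            excl[pos[i], pos[j]] = excl[pos[j], pos[i]] = True
    for i, j in one_four:
        if i in pos and j in pos:
            scaled[pos[i], pos[j]] = scaled[pos[j], pos[i]] = True
    return excl, scaled


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(coords))


def bonded_energy(frame: Frame, selection: Selection, ff: ForceField,
                  topology: Topology | None = None) -> float:
    """Sum of bond, angle and dihedral terms whose atoms lie in the selection.

    Terms entirely outside the selection are skipped (they belong to the other
    molecule); terms straddling the selection boundary raise, since a partial
    bonded term has no physical meaning.
    """
    x = frame.coordinates
    member = np.zeros(x.shape[0], dtype=bool)
    member[selection.atom_indices] = True
    e = 0.0

    if ff.bond_terms:
        t = np.array(ff.bond_terms, dtype=float)
        ij = t[:, :2].astype(int)
        inside = member[ij].sum(axis=1)
        if np.any((inside != 0) & (inside != 2)):
            bad = ij[(inside != 0) & (inside != 2)][0]
            raise ValueError(f"bond term {tuple(bad)} straddles selection boundary")
        keep = inside == 2
        if np.any(keep):
            d = np.linalg.norm(x[ij[keep, 0]] - x[ij[keep, 1]], axis=1)
            e += float((t[keep, 2] * (d - t[keep, 3]) ** 2).sum())

    if ff.angle_terms:
        t = np.array(ff.angle_terms, dtype=float)
        ijk = t[:, :3].astype(int)
        inside = member[ijk].sum(axis=1)
        if np.any((inside != 0) & (inside != 3)):
            bad = ijk[(inside != 0) & (inside != 3)][0]
            raise ValueError(f"angle term {tuple(bad)} straddles selection boundary")
        keep = inside == 3
        if np.any(keep):
            v1 = x[ijk[keep, 0]] - x[ijk[keep, 1]]
            v2 = x[ijk[keep, 2]] - x[ijk[keep, 1]]
            cos_t = (v1 * v2).sum(1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
            e += float((t[keep, 3] * (theta - t[keep, 4]) ** 2).sum())

    if ff.dihedral_terms:
        t = np.array(ff.dihedral_terms, dtype=float)
        ijkl = t[:, :4].astype(int)
        inside = member[ijkl].sum(axis=1)
        if np.any((inside != 0) & (inside != 4)):
            bad = ijkl[(inside != 0) & (inside != 4)][0]
            raise ValueError(
                f"dihedral term {tuple(bad)} straddles selection boundary"
            )
        keep = inside == 4
        if np.any(keep):
            b1 = x[ijkl[keep, 1]] - x[ijkl[keep, 0]]
            b2 = x[ijkl[keep, 2]] - x[ijkl[keep, 1]]
            b3 = x[ijkl[keep, 3]] - x[ijkl[keep, 2]]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            b2u = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
            m1 = np.cross(n1, b2u)
            phi = np.arctan2((m1 * n2).sum(1), (n1 * n2).sum(1))
            e += float(
                (t[keep, 4] * (1.0 + np.cos(t[keep, 5] * phi - t[keep, 6]))).sum()
            )
    return float(e)


def coulomb_energy(frame: Frame, selection: Selection, ff: ForceField,
                   topology: Topology) -> float:
    idx = selection.atom_indices
    n = idx.size
    if n < 2:
        return 0.0
    coords = frame.coordinates[idx]
    q = ff.charges[idx]
    r = _pair_distances(coords)
    excl, scaled = _pair_masks(selection, topology, n)
    iu = np.triu_indices(n, k=1)
    live = ~excl[iu]
    if np.any(r[iu][live] < _MIN_DISTANCE):
        raise ValueError("overlapping atoms: interatomic distance below 0.1 Å")
    qq = np.outer(q, q)
    scale = np.where(scaled, 1.0 / ff.scee, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_pair = K_E * qq * scale / r
    e_pair[excl] = 0.0
    np.fill_diagonal(e_pair, 0.0)
    return float(e_pair[iu].sum())


def lennard_jones_energy(frame: Frame, selection: Selection, ff: ForceField,
                         topology: Topology) -> float:
    idx = selection.atom_indices
    n = idx.size
    if n < 2:
        return 0.0
    coords = frame.coordinates[idx]
    r = _pair_distances(coords)
    excl, scaled = _pair_masks(selection, topology, n)
    iu = np.triu_indices(n, k=1)
    live = ~excl[iu]
    if np.any(r[iu][live] < _MIN_DISTANCE):
        raise ValueError("overlapping atoms: interatomic distance below 0.1 Å")
    rmin = ff.lj_rmin_half[idx][:, None] + ff.lj_rmin_half[idx][None, :]
    eps = np.sqrt(np.outer(ff.lj_epsilon[idx], ff.lj_epsilon[idx]))
    scale = np.where(scaled, 1.0 / ff.scnb, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (rmin / r) ** 6
        e_pair = eps * (sr6 ** 2 - 2.0 * sr6) * scale
    e_pair[excl] = 0.0
    np.fill_diagonal(e_pair, 0.0)
    return float(e_pair[iu].sum())


def mm_energy(frame: Frame, selection: Selection, ff: ForceField,
              topology: Topology) -> MMEnergyBreakdown:
    return MMEnergyBreakdown(
        e_int=bonded_energy(frame, selection, ff),
        e_ele=coulomb_energy(frame, selection, ff, topology),
        e_vdw=lennard_jones_energy(frame, selection, ff, topology),
    )


def pair_interaction_energy(
    frame: Frame, sel_a: Selection, sel_b: Selection, ff: ForceField
) -> tuple[float, float]:
    """Explicit cross-selection (ele, vdw) pair sums, no exclusions.

    Valid when no bonded path connects the two selections (separate chains);
    then E(complex) = E(A) + E(B) + E_inter term by term.
    """
    ia, ib = sel_a.atom_indices, sel_b.atom_indices
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections overlap")
    xa, xb = frame.coordinates[ia], frame.coordinates[ib]
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    if np.any(d < _MIN_DISTANCE):
        raise ValueError("overlapping atoms: interatomic distance below 0.1 Å")
    e_ele = float((K_E * np.outer(ff.charges[ia], ff.charges[ib]) / d).sum())
    rmin = ff.lj_rmin_half[ia][:, None] + ff.lj_rmin_half[ib][None, :]
    eps = np.sqrt(np.outer(ff.lj_epsilon[ia], ff.lj_epsilon[ib]))
    sr6 = (rmin / d) ** 6
    e_vdw = float((eps * (sr6 ** 2 - 2.0 * sr6)).sum())
    return e_ele, e_vdw
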