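"""Synthetic two-chain peptide systems and staged dimerization trajectories.

No dynamics engine is involved: trajectories are constructed geometrically
(rigid-body approach of the two chains, planted hydrogen-bond geometry,
Gaussian coordinate noise).  The construction emulates the statistical
structure the downstream analysis assumes:

* two identical simplified chains (backbone N, H, CA, C, O plus one
  side-chain pseudo-atom per residue) carrying one acidic (-1) and one basic
  (+1) side chain each, arranged so that two inter-chain salt bridges align
  when the chains approach;
* a separation profile whose minima (tight contact) produce minima of the
  MM binding energy and, simultaneously, maxima of the solvation (desolvation)
  energy — the anti-correlated extrema that delimit the stages;
* per-bond occupancy schedules that hold chosen donor/acceptor pairs in
  ideal hydrogen-bond geometry for an exact fraction of frames;
* a multi-temperature replica set in which exactly one temperature holds the
  tightest inter-chain contacts.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

from .model_io import Atom, ForceField, Frame, Selection, Topology, Trajectory

__all__ = [
    "PlantedBond",
    "StagePlan",
    "build_toy_dimer",
    "reference_coordinates",
    "generate_staged_trajectory",
    "generate_replica_set",
]

_RES_SPACING = 3.8  # Å between consecutive residues along the chain axis

# local geometry of one simplified residue (name, element, offset from base)
_RESIDUE_GEOMETRY = [
    ("N", "N", np.array([0.0, 0.0, 0.0])),
    ("H", "H", np.array([0.0, 1.0, 0.0])),
    ("CA", "C", np.array([1.3, -0.6, 0.0])),
    ("SIDE", None, np.array([1.3, -0.6, 2.0])),  # name/element set per residue
    ("C", "C", np.array([2.4, 0.2, 0.0])),
    ("O", "O", np.array([2.4, -1.03, 0.0])),
]

_SIDE_ATOM = {"ALA": ("CB", "C"), "ASP": ("OD", "O"), "LYS": ("NZ", "N")}

_CHARGES = {"N": -0.4, "H": 0.4, "CA": 0.0, "C": 0.5, "O": -0.5,
            "CB": 0.0, "OD": -1.0, "NZ": 1.0}
# The side-chain tips are united atoms standing in for a whole group (CH3,
# COO-, NH3+): deeper Lennard-Jones wells and a larger continuum cavity
# radius than a single heavy atom.  With single-atom parameters the toy
# interface has almost no dispersion surface and the Born self-desolvation
# of the +-1 tips makes every inter-chain separation net repulsive; the
# united-atom values give the contact geometry the most favorable
# inter-chain interaction, as in the peptide dimers the toy emulates.
_LJ = {  # name -> (rmin_half Å, epsilon kcal/mol)
    "N": (1.82, 0.17), "H": (0.60, 0.0157), "CA": (1.91, 0.109),
    "CB": (1.95, 0.40), "C": (1.91, 0.086), "O": (1.66, 0.21),
    "OD": (1.66, 0.40), "NZ": (1.82, 0.40),
}
_RADII = {"H": 1.3, "C": 1.7, "N": 1.55, "O": 1.5}
_TIP_RADIUS = 2.5  # Å, united-atom cavity radius of CB/OD/NZ
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

_K_BOND = 300.0   # kcal/mol/Å²
_K_ANGLE = 50.0   # kcal/mol/rad²
_V_DIHEDRAL = 0.5  # kcal/mol (V_n/2)


def _sequence(n_residues: int) -> list[str]:
    """Residue sequence with one acid/base pair placed symmetrically so the
    two salt bridges align when chain B is flipped onto chain A."""
    p = 1 if n_residues >= 5 else 0
    q = n_residues - 1 - p
    seq = ["ALA"] * n_residues
    seq[p] = "ASP"
    seq[q] = "LYS"
    return seq


def _chain_local_coords(sequence: list[str]) -> tuple[list[tuple[str, str]], np.ndarray]:
    names, coords = [], []
    for i, res in enumerate(sequence):
        base = np.array([i * _RES_SPACING, 0.0, 0.0])
        for name, elem, off in _RESIDUE_GEOMETRY:
            if name == "SIDE":
                name, elem = _SIDE_ATOM[res]
            names.append((name, elem))
            coords.append(base + off)
    return names, np.array(coords)


def build_toy_dimer(
    n_residues_per_chain: int, seed: int = 0
) -> tuple[Topology, ForceField]:
    """Two identical simplified chains with full toy parameterization.

    Each residue contributes backbone N, H, CA, C, O and one side-chain
    pseudo-atom; the acidic (-1) and basic (+1) side chains give each chain a
    net charge of zero and provide the salt-bridge partners.  Bonded
    reference values (b0, theta0, dihedral phase) are taken from the built
    reference geometry, so the unperturbed structure sits at the internal
    energy minimum.  Deterministic for a fixed seed.
    """
    n = n_residues_per_chain
    if not 3 <= n <= 30:
        raise ValueError("n_residues_per_chain must be between 3 and 30")
    seq = _sequence(n)
    names, local = _chain_local_coords(seq)

    atoms: list[Atom] = []
    serial = 0
    for chain in ("A", "B"):
        for i, res in enumerate(seq):
            for k in range(6):
                name, elem = names[i * 6 + k]
                atoms.append(
                    Atom(serial=serial, name=name, residue_name=res,
                         residue_index=i + 1, chain_id=chain, element=elem,
                         mass=_MASSES[elem])
                )
                serial += 1

    bonds: set[tuple[int, int]] = set()
    per_chain = 6 * n
    for c0 in (0, per_chain):
        for i in range(n):
            b = c0 + 6 * i  # N,H,CA,SIDE,C,O
            bonds |= {(b, b + 1), (b, b + 2), (b + 2, b + 3), (b + 2, b + 4),
                      (b + 4, b + 5)}
            if i + 1 < n:
                bonds.add((b + 4, b + 6))
    topology = Topology(
        atoms=tuple(atoms), chains=("A", "B"),
        bonds=frozenset(tuple(sorted(b)) for b in bonds),
    )

    coords = reference_coordinates(topology, separation=12.0)
    charges = np.array([_CHARGES[a.name] for a in atoms])
    rmin_half = np.array([_LJ[a.name][0] for a in atoms])
    epsilon = np.array([_LJ[a.name][1] for a in atoms])
    radii = np.array([
        _TIP_RADIUS if a.name in ("CB", "OD", "NZ") else _RADII[a.element]
        for a in atoms
    ])
    masses = np.array([a.mass for a in atoms])

    adj: dict[int, set[int]] = {}
    for i, j in topology.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    bond_terms = [
        (i, j, _K_BOND, float(np.linalg.norm(coords[i] - coords[j])))
        for i, j in sorted(topology.bonds)
    ]
    angle_terms = []
    for j in sorted(adj):
        nbrs = sorted(adj[j])
        for a_i in range(len(nbrs)):
            for b_i in range(a_i + 1, len(nbrs)):
                i, k = nbrs[a_i], nbrs[b_i]
                v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
                cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle_terms.append(
                    (i, j, k, _K_ANGLE, float(np.arccos(np.clip(cos_t, -1, 1))))
                )
    dihedral_terms = []
    for c0 in (0, per_chain):
        for i in range(n - 1):
            b = c0 + 6 * i
            quad = (b, b + 2, b + 4, b + 6)  # N-CA-C-N(i+1)
            phi = _dihedral_angle(coords, *quad)
            # phase chosen so the reference geometry sits at the minimum
            dihedral_terms.append(
                (quad[0], quad[1], quad[2], quad[3], _V_DIHEDRAL, 2,
                 float((2 * phi - math.pi) % (2 * math.pi)))
            )

    ff = ForceField(
        charges=charges, lj_rmin_half=rmin_half, lj_epsilon=epsilon,
        intrinsic_radius=radii, masses=masses, bond_terms=bond_terms,
        angle_terms=angle_terms, dihedral_terms=dihedral_terms,
    )
    return topology, ff


def _dihedral_angle(x, i, j, k, l) -> float:
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def reference_coordinates(topology: Topology, separation: float) -> np.ndarray:
    """Reference complex coordinates at a given chain separation (Å).

    Chain A lies in the z=0 backbone plane with side chains pointing +z;
    chain B is chain A rotated 180° about the y axis (reversing the residue
    order along x and pointing its side chains -z) and shifted to z =
    ``separation``, so the acidic and basic side-chain tips of opposite
    chains face each other.
    """
    seq = [a.residue_name for a in topology.atoms
           if a.chain_id == "A" and a.name == "N"]
    n = len(seq)
    _, local = _chain_local_coords(seq)
    coords = np.zeros((topology.n_atoms, 3))
    coords[: 6 * n] = local
    flipped = local.copy()
    flipped[:, 0] = -flipped[:, 0]
    flipped[:, 2] = -flipped[:, 2]
    flipped[:, 0] += (n - 1) * _RES_SPACING
    flipped[:, 2] += separation
    coords[6 * n:] = flipped
    return coords


@dataclass(frozen=True)
class PlantedBond:
    """A donor/acceptor pair to hold in ideal hydrogen-bond geometry.

    The donor is the backbone N-H of ``donor_residue`` (1-based) on
    ``donor_chain``; the acceptor atom (side-chain O/N by default, or any
    named N/O atom such as the backbone ``O``) is moved onto the ideal site
    2.9 Å from the donor along the N-H direction in scheduled frames.

    Exactly one of ``occupancy`` (fraction of frames, scheduled at seeded
    random positions with an exact count) or ``frames`` (explicit indices)
    must be given.
    """

    donor_chain: str
    donor_residue: int
    acceptor_chain: str
    acceptor_residue: int
    acceptor_atom: str | None = None
    occupancy: float | None = None
    frames: tuple[int, ...] | None = None

    def mask(self, n_frames: int, seed: int, index: int) -> np.ndarray:
        if (self.occupancy is None) == (self.frames is None):
            raise ValueError("specify exactly one of occupancy or frames")
        mask = np.zeros(n_frames, dtype=bool)
        if self.frames is not None:
            mask[list(self.frames)] = True
        else:
            count = int(round(self.occupancy * n_frames))
            rng = np.random.default_rng([seed & 0x7FFFFFFF, index])
            mask[rng.permutation(n_frames)[:count]] = True
        return mask


@dataclass(frozen=True)
class StagePlan:
    """Blueprint of a staged dimerization trajectory.

    ``boundaries`` are the planted stage delimiters: frames where the chain
    separation dips to ``contact_separation``, producing the joint minimum-MM
    / maximum-solvation extremum.  ``stage_separations`` (one per stage,
    i.e. ``len(boundaries) + 1`` values) set the plateau separation inside
    each stage.
    """

    n_frames: int
    boundaries: tuple[int, ...] = ()
    stage_separations: tuple[float, ...] | None = None
    contact_separation: float = 7.0
    well_width: int | None = None
    contact_schedule: tuple[PlantedBond, ...] = ()
    noise: float = 0.08
    seed: int = 0
    dt: float = 4.0

    def __post_init__(self):
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        if b and (b[0] < 0 or b[-1] >= self.n_frames):
            raise ValueError("boundaries must lie within the frame range")
        if self.noise < 0:
            raise ValueError("noise amplitude must be non-negative")
        if self.stage_separations is not None and (
            len(self.stage_separations) != len(b) + 1
        ):
            raise ValueError("need one stage separation per stage")

    @classmethod
    def default(cls, n_frames: int, seed: int = 0, **kwargs) -> "StagePlan":
        """Four-stage plan with delimiters at the fractions of the trajectory
        where the study conditions place them (~0.147, 0.358, 0.616, 0.958
        of the window)."""
        fractions = (0.147, 0.358, 0.616, 0.958)
        boundaries = tuple(int(round(f * (n_frames - 1))) for f in fractions)
        return cls(
            n_frames=n_frames, boundaries=boundaries,
            stage_separations=(12.0, 10.5, 13.0, 9.5, 11.0),
            seed=seed, **kwargs,
        )

    def separation_profile(self) -> np.ndarray:
        """Per-frame chain separation: stage plateaus with Gaussian wells
        dipping to ``contact_separation`` at each boundary."""
        n = self.n_frames
        seps = self.stage_separations or (12.0,) * (len(self.boundaries) + 1)
        edges = [0, *self.boundaries, n]
        prof = np.empty(n)
        for s in range(len(edges) - 1):
            prof[edges[s]: edges[s + 1]] = seps[min(s, len(seps) - 1)]
        w = self.well_width or max(3, n // 60)
        t = np.arange(n, dtype=float)
        c = self.contact_separation
        for b in self.boundaries:
            # multiplicative well: the profile reaches exactly the contact
            # separation at the boundary from both sides, so the planted
            # index is the true minimum even between unequal plateaus
            gauss = np.exp(-((t - b) ** 2) / (2.0 * w ** 2))
            prof = c + (prof - c) * (1.0 - gauss)
        return np.maximum(prof, c)


def _atom_index(topology: Topology, chain: str, residue: int, name: str) -> int:
    for a in topology.atoms:
        if a.chain_id == chain and a.residue_index == residue and a.name == name:
            return a.serial
    raise ValueError(f"no atom {chain}:{residue}:{name} in topology")


def _acceptor_index(topology: Topology, bond: PlantedBond) -> int:
    if bond.acceptor_atom is not None:
        return _atom_index(topology, bond.acceptor_chain, bond.acceptor_residue,
                           bond.acceptor_atom)
    for name in ("OD", "NZ", "O"):
        try:
            return _atom_index(topology, bond.acceptor_chain,
                               bond.acceptor_residue, name)
        except ValueError:
            continue
    raise ValueError(
        f"residue {bond.acceptor_chain}:{bond.acceptor_residue} has no N/O "
        "acceptor atom"
    )


_MAX_RETRIES = 10
_MIN_CLEARANCE = 0.5  # Å


def generate_staged_trajectory(topology: Topology, plan: StagePlan) -> Trajectory:
    """Construct the staged trajectory described by ``plan``.

    Frames are the reference complex at the per-frame separation, with
    scheduled acceptor atoms moved into ideal hydrogen-bond geometry and
    Gaussian coordinate noise on every atom.  Frames whose noise produces an
    atomic overlap (< 0.5 Å) are redrawn up to a retry cap.
    """
    rng = np.random.default_rng(plan.seed & 0x7FFFFFFF)
    separations = plan.separation_profile()
    masks = [
        (b, b.mask(plan.n_frames, plan.seed, k), _acceptor_index(topology, b),
         _atom_index(topology, b.donor_chain, b.donor_residue, "N"),
         _atom_index(topology, b.donor_chain, b.donor_residue, "H"))
        for k, b in enumerate(plan.contact_schedule)
    ]
    frames = []
    for fi in range(plan.n_frames):
        base = reference_coordinates(topology, separations[fi])
        for bond, mask, acc, don, hyd in masks:
            if mask[fi]:
                unit = base[hyd] - base[don]
                unit /= np.linalg.norm(unit)
                base[acc] = base[don] + 2.9 * unit
        for attempt in range(_MAX_RETRIES + 1):
            coords = base + rng.normal(0.0, plan.noise, base.shape) \
                if plan.noise > 0 else base.copy()
            if plan.noise == 0 or pdist(coords).min() >= _MIN_CLEARANCE:
                break
        else:
            raise RuntimeError(
                f"frame {fi}: atoms closer than {_MIN_CLEARANCE} Å after "
                f"{_MAX_RETRIES} redraws"
            )
        frames.append(Frame(coordinates=coords, time=plan.dt * (fi + 1)))
    return Trajectory(topology=topology, frames=tuple(frames), dt=plan.dt)


def generate_replica_set(
    topology: Topology,
    temperatures,
    seed: int = 0,
    n_frames: int = 60,
    dt: float = 40.0,
    best_temperature: float | None = 305.0,
    contact_separation: float = 7.0,
    loose_separation: float = 11.0,
) -> list[Trajectory]:
    """One trajectory per temperature, in input order.

    Coordinate-noise amplitude scales with sqrt(T/305); the replica at
    ``best_temperature`` (nearest match) holds the tightest inter-chain
    contacts, all others sit at ``loose_separation`` or farther.
    """
    temps = list(temperatures)
    if not temps:
        raise ValueError("temperature list is empty")
    if best_temperature is None:
        best_idx = 0
    else:
        best_idx = int(np.argmin([abs(t - best_temperature) for t in temps]))
    out = []
    for k, temp in enumerate(temps):
        sep = contact_separation if k == best_idx else (
            loose_separation + 0.02 * abs(temp - temps[best_idx])
        )
        plan = StagePlan(
            n_frames=n_frames,
            stage_separations=(sep,),
            contact_separation=contact_separation,
            noise=0.06 * math.sqrt(temp / 305.0),
            seed=(seed & 0x3FFFFFFF) + 7919 * k,
            dt=dt,
        )
        out.append(generate_staged_trajectory(topology, plan))
    return out
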