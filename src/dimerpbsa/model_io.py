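"""Topology, trajectory and force-field I/O.

File formats are handled through MDAnalysis (PDB with ATOM/MODEL/ENDMDL/CONECT
records, DCD) and PyYAML/JSON for the force-field parameter file.  Internally
everything is 0-based; the file formats keep their native 1-based serials.

The force-field file is a YAML or JSON document with the schema::

    atoms:      # one entry per topology atom, in file order
      - {name: N, chain: A, charge: -0.4, rmin_half: 1.82, epsilon: 0.17,
         radius: 1.55, mass: 14.007}
    bonds:      # 1-based atom serials
      - {i: 1, j: 2, k: 434.0, b0: 1.01}
    angles:
      - {i: 1, j: 2, k_idx: 3, k_theta: 80.0, theta0: 1.91}   # theta0 in rad
    dihedrals:
      - {i: 1, j: 2, k_idx: 3, l: 4, v2: 1.4, n: 2, gamma: 3.14159}
    scee: 1.2
    scnb: 2.0
"""

from __future__ import annotations

import io
import json
import math
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "ForceField",
    "read_topology",
    "read_trajectory",
    "read_forcefield",
    "write_pdb",
    "write_dcd",
    "write_forcefield",
    "select_chain",
    "sample_frames",
]

# Masses by element for atoms read from plain PDB files (amu).
_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# Residue templates used for bond inference on the simplified residues this
# package generates (backbone N,H,CA,C,O plus a single side-chain pseudo-atom).
_RESIDUE_TEMPLATES = {
    "ALA": [("N", "H"), ("N", "CA"), ("CA", "CB"), ("CA", "C"), ("C", "O")],
    "ASP": [("N", "H"), ("N", "CA"), ("CA", "OD"), ("CA", "C"), ("C", "O")],
    "LYS": [("N", "H"), ("N", "CA"), ("CA", "NZ"), ("CA", "C"), ("C", "O")],
    "GLY": [("N", "H"), ("N", "CA"), ("CA", "C"), ("C", "O")],
}

_NAME_TO_ELEMENT = {
    "N": "N", "H": "H", "CA": "C", "CB": "C", "C": "C", "O": "O",
    "OD": "O", "NZ": "N",
}


@dataclass(frozen=True)
class Atom:
    """One atom of the topology (0-based ``serial``)."""

    serial: int
    name: str
    residue_name: str
    residue_index: int
    chain_id: str
    element: str
    mass: float


@dataclass(frozen=True)
class Topology:
    atoms: tuple[Atom, ...]
    chains: tuple[str, ...]
    bonds: frozenset[tuple[int, int]]

    def __post_init__(self):
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references atom outside topology")
            if self.atoms[i].chain_id != self.atoms[j].chain_id:
                raise ValueError(
                    f"bond ({i}, {j}) crosses chains "
                    f"{self.atoms[i].chain_id}/{self.atoms[j].chain_id}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_indices(self, chain_id: str) -> np.ndarray:
        return np.array(
            [a.serial for a in self.atoms if a.chain_id == chain_id], dtype=int
        )

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass(frozen=True)
class Frame:
    coordinates: np.ndarray  # (n_atoms, 3), Å
    time: float  # ps

    def __post_init__(self):
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", c)


@dataclass(frozen=True)
class Trajectory:
    topology: Topology
    frames: tuple[Frame, ...]
    dt: float  # ps between stored frames

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(steps - self.dt) > 1e-6 * max(self.dt, 1.0)):
                raise ValueError("frame spacing is not uniform at the stated dt")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class Selection:
    label: str  # "complex", "A" or "B"
    atom_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("atom_indices must be strictly ascending")
        object.__setattr__(self, "atom_indices", idx)

    @property
    def n_atoms(self) -> int:
        return self.atom_indices.size


@dataclass
class ForceField:
    """Per-atom and bonded parameters (toy schema, Amber functional forms)."""

    charges: np.ndarray        # e
    lj_rmin_half: np.ndarray   # Å
    lj_epsilon: np.ndarray     # kcal/mol
    intrinsic_radius: np.ndarray  # Å (PB/GB cavity radii)
    masses: np.ndarray         # amu
    bond_terms: list[tuple[int, int, float, float]] = field(default_factory=list)
    angle_terms: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedral_terms: list[tuple[int, int, int, int, float, int, float]] = field(
        default_factory=list
    )
    scee: float = 1.2
    scnb: float = 2.0

    def __post_init__(self):
        for name in ("charges", "lj_rmin_half", "lj_epsilon", "intrinsic_radius", "masses"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.lj_epsilon < 0):
            raise ValueError("negative Lennard-Jones epsilon")
        if np.any(self.intrinsic_radius <= 0):
            raise ValueError("intrinsic radii must be positive")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return self.charges.size


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _mda_universe_from_pdb_text(pdb_text: str):
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(NamedStream(io.StringIO(pdb_text), "topology.pdb"))


def read_topology(pdb_text: str, require_dimer: bool = True) -> Topology:
    """Parse a PDB text into a :class:`Topology`.

    Bonds are inferred from built-in residue templates for the simplified
    residues; CONECT records are honoured when present.  Bonds never cross
    chains (the two peptides of a dimer are separate molecules).
    """
    if os.linesep != "\n":  # pragma: no cover
        pdb_text = pdb_text.replace(os.linesep, "\n")
    u = _mda_universe_from_pdb_text(pdb_text)
    chain_ids = [str(c).strip() for c in u.atoms.chainIDs]
    for rec, cid in enumerate(chain_ids):
        if not cid:
            raise ValueError(f"ATOM record {rec + 1} has no chain identifier")
    chains = tuple(dict.fromkeys(chain_ids))
    if require_dimer and len(chains) != 2:
        raise ValueError(
            f"dimer analysis requires exactly 2 chains, found {len(chains)}: {chains}"
        )

    atoms = []
    for k, a in enumerate(u.atoms):
        name = str(a.name).strip()
        element = _NAME_TO_ELEMENT.get(name)
        if element is None:
            element = str(getattr(a, "element", "") or name[0]).strip() or name[0]
        mass = _ELEMENT_MASSES.get(element, float(getattr(a, "mass", 0.0)) or 12.011)
        atoms.append(
            Atom(
                serial=k,
                name=name,
                residue_name=str(a.resname).strip(),
                residue_index=int(a.resid),
                chain_id=chain_ids[k],
                element=element,
                mass=mass,
            )
        )

    bonds: set[tuple[int, int]] = set()
    # template bonds within residues + backbone link between consecutive resids
    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    for a in atoms:
        by_residue.setdefault((a.chain_id, a.residue_index), {})[a.name] = a.serial
    for (cid, rid), names in by_residue.items():
        template = _RESIDUE_TEMPLATES.get(atoms[next(iter(names.values()))].residue_name)
        if template:
            for n1, n2 in template:
                if n1 in names and n2 in names:
                    bonds.add(tuple(sorted((names[n1], names[n2]))))
        nxt = by_residue.get((cid, rid + 1))
        if nxt and "C" in names and "N" in nxt:
            bonds.add(tuple(sorted((names["C"], nxt["N"]))))
    # CONECT records
    if hasattr(u, "bonds"):
        for b in u.bonds:
            i, j = int(b.indices[0]), int(b.indices[1])
            if atoms[i].chain_id == atoms[j].chain_id:
                bonds.add(tuple(sorted((i, j))))

    return Topology(atoms=tuple(atoms), chains=chains, bonds=frozenset(bonds))


def read_trajectory(
    source: str | Path, topology: Topology, dt: float | None = None
) -> Trajectory:
    """Read a multi-model PDB or a DCD file into a :class:`Trajectory`.

    ``dt`` (ps) overrides the file header; multi-model PDB files carry no time
    information, so ``dt`` defaults to 4.0 ps there.
    """
    import MDAnalysis as mda

    source = Path(source)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if source.suffix.lower() == ".dcd":
            n = topology.n_atoms
            u = mda.Universe.empty(n, trajectory=True)
            u.load_new(str(source))
            if dt is None:
                dt = float(u.trajectory.dt)
        else:
            u = mda.Universe(str(source))
            if dt is None:
                dt = 4.0
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError(
                f"trajectory has {u.atoms.n_atoms} atoms, topology has "
                f"{topology.n_atoms}"
            )
        coords = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
    if not coords:
        raise ValueError("trajectory contains zero frames")
    frames = tuple(
        Frame(coordinates=c, time=dt * (k + 1)) for k, c in enumerate(coords)
    )
    return Trajectory(topology=topology, frames=frames, dt=float(dt))


def read_forcefield(source: str | Path | dict, topology: Topology) -> ForceField:
    """Read the force-field parameter file (YAML/JSON) and validate coverage."""
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    atoms_doc = doc.get("atoms", [])
    n = topology.n_atoms
    if len(atoms_doc) != n:
        raise ValueError(
            f"parameter file lists {len(atoms_doc)} atoms, topology has {n}"
        )
    fields = {"charge": [], "rmin_half": [], "epsilon": [], "radius": [], "mass": []}
    for k, (entry, atom) in enumerate(zip(atoms_doc, topology.atoms)):
        if entry.get("name") != atom.name or entry.get("chain") != atom.chain_id:
            raise ValueError(
                f"parameter entry {k + 1} ({entry.get('chain')}:{entry.get('name')}) "
                f"does not match topology atom {atom.chain_id}:{atom.name}"
            )
        for key, store in fields.items():
            if key not in entry:
                raise ValueError(
                    f"atom {atom.chain_id}:{atom.residue_name}{atom.residue_index}:"
                    f"{atom.name} lacks parameter '{key}'"
                )
            store.append(float(entry[key]))

    def _idx(v):  # 1-based file serials -> 0-based
        return int(v) - 1

    bond_terms = [
        (_idx(b["i"]), _idx(b["j"]), float(b["k"]), float(b["b0"]))
        for b in doc.get("bonds", [])
    ]
    angle_terms = [
        (_idx(a["i"]), _idx(a["j"]), _idx(a["k_idx"]), float(a["k_theta"]),
         float(a["theta0"]))
        for a in doc.get("angles", [])
    ]
    dihedral_terms = [
        (_idx(d["i"]), _idx(d["j"]), _idx(d["k_idx"]), _idx(d["l"]),
         float(d["v2"]), int(d["n"]), float(d["gamma"]))
        for d in doc.get("dihedrals", [])
    ]
    return ForceField(
        charges=fields["charge"],
        lj_rmin_half=fields["rmin_half"],
        lj_epsilon=fields["epsilon"],
        intrinsic_radius=fields["radius"],
        masses=fields["mass"],
        bond_terms=bond_terms,
        angle_terms=angle_terms,
        dihedral_terms=dihedral_terms,
        scee=float(doc.get("scee", 1.2)),
        scnb=float(doc.get("scnb", 2.0)),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _mda_universe_from_topology(topology: Topology):
    import MDAnalysis as mda

    residue_keys = list(
        dict.fromkeys((a.chain_id, a.residue_index) for a in topology.atoms)
    )
    res_of = {key: k for k, key in enumerate(residue_keys)}
    atom_resindex = [res_of[(a.chain_id, a.residue_index)] for a in topology.atoms]
    seg_of = {c: k for k, c in enumerate(topology.chains)}
    residue_segindex = [seg_of[key[0]] for key in residue_keys]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            topology.n_atoms,
            n_residues=len(residue_keys),
            n_segments=len(topology.chains),
            atom_resindex=atom_resindex,
            residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
        u.add_TopologyAttr(
            "resnames",
            [topology.atoms[[a.serial for a in topology.atoms
                             if (a.chain_id, a.residue_index) == key][0]].residue_name
             for key in residue_keys],
        )
        u.add_TopologyAttr("resids", [key[1] for key in residue_keys])
        u.add_TopologyAttr(
            "chainIDs", [a.chain_id for a in topology.atoms]
        )
        u.add_TopologyAttr("segids", list(topology.chains))
        if topology.bonds:
            u.add_TopologyAttr("bonds", sorted(topology.bonds))
    return u


def write_pdb(
    topology: Topology,
    frames: Frame | Sequence[Frame] | Trajectory,
    path: str | Path,
) -> Path:
    """Write a (multi-model) PDB; CONECT records carry the topology bonds."""
    import MDAnalysis as mda

    if isinstance(frames, Trajectory):
        frames = frames.frames
    elif isinstance(frames, Frame):
        frames = [frames]
    u = _mda_universe_from_topology(topology)
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=len(frames) > 1, bonds="all") as w:
            for f in frames:
                u.atoms.positions = f.coordinates
                w.write(u.atoms)
    return path


def write_dcd(trajectory: Trajectory, path: str | Path) -> Path:
    import MDAnalysis as mda

    u = _mda_universe_from_topology(trajectory.topology)
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(
            str(path), n_atoms=trajectory.topology.n_atoms, dt=trajectory.dt
        ) as w:
            for f in trajectory.frames:
                u.atoms.positions = f.coordinates
                w.write(u.atoms)
    return path


def write_forcefield(
    ff: ForceField, topology: Topology, path: str | Path
) -> Path:
    doc = {
        "atoms": [
            {
                "name": a.name,
                "chain": a.chain_id,
                "charge": float(ff.charges[k]),
                "rmin_half": float(ff.lj_rmin_half[k]),
                "epsilon": float(ff.lj_epsilon[k]),
                "radius": float(ff.intrinsic_radius[k]),
                "mass": float(ff.masses[k]),
            }
            for k, a in enumerate(topology.atoms)
        ],
        "bonds": [
            {"i": i + 1, "j": j + 1, "k": k, "b0": b0}
            for i, j, k, b0 in ff.bond_terms
        ],
        "angles": [
            {"i": i + 1, "j": j + 1, "k_idx": k + 1, "k_theta": kt, "theta0": t0}
            for i, j, k, kt, t0 in ff.angle_terms
        ],
        "dihedrals": [
            {"i": i + 1, "j": j + 1, "k_idx": k + 1, "l": l + 1,
             "v2": v, "n": n, "gamma": g}
            for i, j, k, l, v, n, g in ff.dihedral_terms
        ],
        "scee": ff.scee,
        "scnb": ff.scnb,
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# selections & sampling
# ---------------------------------------------------------------------------

def select_chain(topology: Topology, which: str) -> Selection:
    """Selection for ``"complex"`` (all atoms) or one chain (``"A"``/``"B"``)."""
    if which == "complex":
        return Selection("complex", np.arange(topology.n_atoms))
    if which in topology.chains:
        return Selection(which, topology.chain_indices(which))
    raise ValueError(
        f"unknown selection {which!r}; expected 'complex' or one of {topology.chains}"
    )


def sample_frames(
    trajectory: Trajectory, interval: float, window: float
) -> Trajectory:
    """Keep every (interval/dt)-th frame from the final ``window`` ns.

    The window is half-open: the last frame is included, the window start is
    excluded, so a 19 ns window at 4 ps spacing yields exactly 4750 frames.

    Parameters
    ----------
    interval : sampling interval in ps (must be a multiple of the stored dt)
    window : length of the trailing window in ns
    """
    dt = trajectory.dt
    stride_f = interval / dt
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-6 * stride_f:
        raise ValueError(f"interval {interval} ps is not a multiple of dt {dt} ps")
    n_out = int(math.floor(window * 1000.0 / interval + 1e-9))
    if n_out < 1:
        raise ValueError("window shorter than one sampling interval")
    last = trajectory.n_frames - 1
    first = last - (n_out - 1) * stride
    if first < 0:
        raise ValueError(
            f"window {window} ns at {interval} ps needs {n_out} frames at stride "
            f"{stride}; trajectory has only {trajectory.n_frames}"
        )
    kept = trajectory.frames[first:: stride] if stride > 0 else trajectory.frames
    kept = kept[:n_out] if len(kept) != n_out else kept
    # renumber times on the sampled grid, preserving absolute times
    return Trajectory(topology=trajectory.topology, frames=tuple(kept), dt=interval)
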