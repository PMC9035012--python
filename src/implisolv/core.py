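"""Molecular data model: topology, conformations, trajectories, selections.

Atom indices are 0-based internally; residue numbers are kept exactly as in
the source structure (1-based for PDB files).  Coordinates are in nm.
Hydrogens that a united-atom topology does not carry are never dynamic
particles; they exist only as virtual/pseudo sites constructed at
observable-calculation time (see :mod:`implisolv.observables`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Conformation",
    "Trajectory",
    "select_atoms",
    "center_of_mass",
]

#: The 23 GROMOS-compatible SASA atom-type codes.
SASA_TYPE_CODES = (
    "O", "OM", "OA", "OE", "OW", "N", "NT", "NL", "NR", "NZ", "NE",
    "C", "CH0", "CH1", "CH2", "CH3", "CH4", "CH2r", "CR1", "HC", "H",
    "DUM", "S",
)

#: Standard atomic masses (u) by element, plus united-atom aggregates by type.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.06,
}

UNITED_ATOM_MASSES = {
    "CH1": 13.019,
    "CH2": 14.027,
    "CH2r": 14.027,
    "CH3": 15.035,
    "CH4": 16.043,
    "CR1": 13.019,
}


def mass_for(element: str, sasa_type: str) -> float:
    """Default mass: united-atom aggregate if the type is a CHn group,
    otherwise the standard atomic mass of the element."""
    if sasa_type in UNITED_ATOM_MASSES:
        return UNITED_ATOM_MASSES[sasa_type]
    try:
        return ELEMENT_MASSES[element]
    except KeyError:
        raise ValueError(f"no default mass for element {element!r}") from None


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    mass: float
    sasa_type: str
    residue_index: int
    residue_name: str


class Topology:
    """Atoms, covalent bonds and holonomic bond-length constraints.

    Parameters
    ----------
    atoms
        Sequence of :class:`Atom`.
    bonds
        Index pairs (0-based) of covalently bound atoms.
    constraints
        Triples ``(i, j, d0)`` fixing the i–j distance at ``d0`` nm.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Iterable[tuple[int, int]] = (),
        constraints: Iterable[tuple[int, int, float]] = (),
    ):
        self.atoms = list(atoms)
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in bonds]
        self.constraints = [(int(i), int(j), float(d)) for i, j, d in constraints]
        n = len(self.atoms)
        for a in self.atoms:
            if a.mass <= 0:
                raise ValueError(f"non-positive mass for atom {a.name}")
            if a.sasa_type not in SASA_TYPE_CODES:
                raise ValueError(f"unknown SASA type code {a.sasa_type!r}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atoms")
        for i, j, d in self.constraints:
            if not (0 <= i < n and 0 <= j < n) or i == j or d <= 0:
                raise ValueError(f"invalid constraint ({i},{j},{d})")
        self._neighbour_order: dict[tuple[int, int], int] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def sasa_types(self) -> list[str]:
        return [a.sasa_type for a in self.atoms]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    def bonded_neighbours(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def neighbour_order(self, i: int, j: int) -> int:
        """Covalent separation: 1 for bonded first neighbours, 2 for second
        neighbours, 3 for anything further (or disconnected)."""
        if self._neighbour_order is None:
            self._neighbour_order = {}
            adj = self.bonded_neighbours()
            for a, nbrs in enumerate(adj):
                for b in nbrs:
                    self._neighbour_order[(a, b)] = 1
            for a, nbrs in enumerate(adj):
                for b in nbrs:
                    for c in adj[b]:
                        if c != a and (a, c) not in self._neighbour_order:
                            self._neighbour_order[(a, c)] = 2
        return self._neighbour_order.get((i, j), 3)

    def is_hydrogen(self, i: int) -> bool:
        return self.atoms[i].element == "H"


@dataclass
class Conformation:
    """Cartesian coordinates (nm) for one configuration; vacuum boundary."""

    coordinates: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered conformations sharing one topology, with time stamps in ps."""

    topology: Topology
    frames: list[Conformation] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times differ in length")
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        for f in self.frames:
            if f.n_atoms != self.topology.n_atoms:
                raise ValueError("frame atom count does not match topology")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def coordinates(self) -> np.ndarray:
        """All frames stacked as an (n_frames, N, 3) array."""
        return np.array([f.coordinates for f in self.frames])

    def append(self, conf: Conformation, time: float) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        if conf.n_atoms != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        self.frames.append(conf)
        self.times.append(float(time))


def _parse_resid_clause(spec: str) -> set[int]:
    out: set[int] = set()
    for part in spec.replace(",", " ").split():
        if "-" in part[1:]:  # allow negative single ids, not used in practice
            lo, hi = part.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return out


def select_atoms(topology: Topology, selection: str) -> list[int]:
    """Resolve a selection expression to an ordered, duplicate-free index list.

    The mini-language supports ``all``, ``name <list>`` and ``resid <a>-<b>``
    (or a comma/space-separated list of residue numbers), joined with ``and``.
    Unknown atom names in a ``name`` clause raise, naming the offending atom.
    """
    keep = np.ones(topology.n_atoms, dtype=bool)
    clauses = [c.strip() for c in selection.split(" and ")]
    names = topology.names
    present = set(names)
    for clause in clauses:
        if not clause:
            raise ValueError("empty selection clause")
        if clause == "all":
            continue
        key, _, rest = clause.partition(" ")
        if key == "name":
            wanted = [w for w in rest.replace(",", " ").split() if w]
            if not wanted:
                raise ValueError("'name' clause without atom names")
            for w in wanted:
                if w not in present:
                    raise ValueError(f"unknown atom name {w!r} in selection")
            wset = set(wanted)
            keep &= np.array([nm in wset for nm in names])
        elif key == "resid":
            rset = _parse_resid_clause(rest)
            keep &= np.isin(topology.residue_indices, sorted(rset))
        else:
            raise ValueError(f"unknown selection keyword {key!r}")
    return [int(i) for i in np.flatnonzero(keep)]


def center_of_mass(conf: Conformation, topology: Topology) -> np.ndarray:
    """Mass-weighted mean position (nm)."""
    m = topology.masses
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return (m[:, None] * conf.coordinates).sum(axis=0) / total
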