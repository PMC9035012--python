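"""Readers and writers for on-disk artifacts.

Coordinates are nm internally; the PDB Angstrom convention is converted at
the boundary.  Restraint and experimental tables are tab-separated with a
mandatory header; ``#`` lines are comments.  Trajectories round-trip
losslessly in a plain-text frame format and at 1e-3 nm in multi-model PDB.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Atom, Conformation, Topology, Trajectory, ELEMENT_MASSES, mass_for
from .observables import NOERestraint
from .units import NM_PER_ANGSTROM

__all__ = [
    "PDBRecordOptions",
    "read_pdb",
    "write_pdb",
    "write_topology",
    "read_topology",
    "write_trajectory",
    "read_trajectory",
    "read_table",
    "write_table",
    "parse_sd_config",
    "TABLE_SCHEMAS",
]

#: Map from inferred element to a default SASA type code for PDB input.
_ELEMENT_TYPE = {"N": "N", "O": "O", "C": "C", "S": "S", "H": "HC"}


@dataclass(frozen=True)
class PDBRecordOptions:
    """altloc_policy: 'highest-occupancy' keeps the conformation with the
    largest occupancy, 'first' the first encountered, 'error' refuses
    disordered input."""

    altloc_policy: str = "highest-occupancy"
    model_selection: str = "all"  # or "first"
    chain: str | None = None
    keep_hydrogens: bool = True

    def __post_init__(self):
        if self.altloc_policy not in ("highest-occupancy", "first", "error"):
            raise ValueError(f"unknown altloc policy {self.altloc_policy!r}")


def _infer_element(atom_name: str, pdb_element: str) -> str:
    el = pdb_element.strip().capitalize()
    if el in ELEMENT_MASSES:
        return el
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


def _prevalidate_pdb(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}:{lineno}: truncated ATOM record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: malformed coordinates in ATOM record"
                    ) from None


def read_pdb(
    path,
    options: PDBRecordOptions = PDBRecordOptions(),
    type_overrides: dict | None = None,
):
    """Parse a PDB file into (Topology, Trajectory).

    Multi-model files become multi-frame trajectories (1 ps nominal frame
    spacing).  SASA atom types default from the element and may be refined
    via ``type_overrides`` keyed by (residue_name, atom_name).  Bonds are
    not inferred from a PDB file.
    """
    from Bio.PDB import PDBParser

    _prevalidate_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    type_overrides = type_overrides or {}

    models = list(structure)
    if options.model_selection == "first":
        models = models[:1]
    atoms_meta = None
    frames = []
    for model in models:
        coords = []
        meta = []
        for chain in model:
            if options.chain is not None and chain.id != options.chain:
                continue
            for residue in chain:
                if residue.id[0].strip():  # skip waters/heteros
                    continue
                for atom in residue:
                    if atom.is_disordered():
                        kids = atom.disordered_get_list()
                        if options.altloc_policy == "error":
                            raise ValueError(
                                f"disordered atom {atom.get_id()} in residue "
                                f"{residue.id[1]} under altloc policy 'error'"
                            )
                        if options.altloc_policy == "first":
                            chosen = kids[0]
                        else:
                            chosen = max(kids, key=lambda a: a.get_occupancy() or 0.0)
                    else:
                        chosen = atom
                    el = _infer_element(chosen.get_name(), chosen.element or "")
                    if el == "H" and not options.keep_hydrogens:
                        continue
                    coords.append(chosen.get_coord() * NM_PER_ANGSTROM)
                    meta.append(
                        (chosen.get_name(), el, residue.id[1], residue.get_resname())
                    )
        if atoms_meta is None:
            atoms_meta = meta
        frames.append(np.array(coords))

    atoms = []
    for name, el, resid, resname in atoms_meta:
        code = type_overrides.get((resname, name), _ELEMENT_TYPE.get(el, "C"))
        atoms.append(
            Atom(
                name=name,
                element=el,
                mass=mass_for(el, code),
                sasa_type=code,
                residue_index=resid,
                residue_name=resname,
            )
        )
    topo = Topology(atoms)
    traj = Trajectory(
        topo,
        [Conformation(f) for f in frames],
        [float(k) for k in range(len(frames))],
        {"source": str(path)},
    )
    return topo, traj


def write_pdb(traj: Trajectory, path) -> None:
    """Write a (multi-model) PDB file at the format's 1e-3 nm precision."""
    topo = traj.topology
    with open(path, "w") as fh:
        for n_model, conf in enumerate(traj.frames, start=1):
            if len(traj.frames) > 1:
                fh.write(f"MODEL     {n_model:4d}\n")
            for k, atom in enumerate(topo.atoms):
                x, y, z = conf.coordinates[k] / NM_PER_ANGSTROM
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {k + 1:5d} {name:<4s}{atom.residue_name:>4s} A"
                    f"{atom.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            if len(traj.frames) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_topology(topology: Topology, path) -> None:
    """Write a topology (atoms, bonds, constraints) as a plain-text table.

    PDB records cannot carry united-atom SASA type codes or the bond graph,
    so analyses on united-atom models use this format alongside the PDB."""
    with open(path, "w") as fh:
        fh.write("# implisolv-topology 1\n")
        fh.write("[atoms]\nname\telement\tmass\tsasa_type\tresidue\tresname\n")
        for a in topology.atoms:
            fh.write(
                f"{a.name}\t{a.element}\t{a.mass!r}\t{a.sasa_type}\t"
                f"{a.residue_index}\t{a.residue_name}\n"
            )
        fh.write("[bonds]\n")
        for i, j in topology.bonds:
            fh.write(f"{i}\t{j}\n")
        fh.write("[constraints]\n")
        for i, j, d in topology.constraints:
            fh.write(f"{i}\t{j}\t{d!r}\n")


def read_topology(path) -> Topology:
    """Read the plain-text topology format back."""
    atoms, bonds, constraints = [], [], []
    section = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            if section == "atoms":
                if line.startswith("name\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ValueError(f"{path}:{lineno}: malformed atom row")
                atoms.append(
                    Atom(parts[0], parts[1], float(parts[2]), parts[3],
                         int(parts[4]), parts[5])
                )
            elif section == "bonds":
                i, j = line.split("\t")
                bonds.append((int(i), int(j)))
            elif section == "constraints":
                i, j, d = line.split("\t")
                constraints.append((int(i), int(j), float(d)))
            else:
                raise ValueError(f"{path}:{lineno}: content outside a section")
    return Topology(atoms, bonds, constraints)


def load_topology(path) -> Topology:
    """Dispatch on extension: .pdb via read_pdb, otherwise the text format."""
    if str(path).endswith(".pdb"):
        topo, _ = read_pdb(path)
        return topo
    return read_topology(path)


def write_trajectory(traj: Trajectory, path, fmt: str = "text", thin: int = 1):
    """Write a trajectory; 'text' round-trips at full precision, 'pdb' at
    PDB precision.  ``thin`` keeps every thin-th frame."""
    if fmt == "pdb":
        thinned = Trajectory(
            traj.topology,
            traj.frames[::thin],
            traj.times[::thin],
            dict(traj.metadata),
        )
        write_pdb(thinned, path)
        return
    if fmt != "text":
        raise ValueError(f"unknown trajectory format {fmt!r}")
    n = traj.topology.n_atoms
    with open(path, "w") as fh:
        fh.write("# implisolv-traj 1\n")
        fh.write(f"natoms {n}\n")
        for conf, t in zip(traj.frames[::thin], traj.times[::thin]):
            fh.write(f"frame {float(t)!r}\n")
            for i, (x, y, z) in enumerate(conf.coordinates):
                fh.write(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Read the plain-text frame format back into a Trajectory."""
    frames, times = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# implisolv-traj"):
            raise ValueError(f"{path}:1: not an implisolv trajectory file")
        line = fh.readline()
        if not line.startswith("natoms"):
            raise ValueError(f"{path}:2: missing natoms header")
        n = int(line.split()[1])
        if n != topology.n_atoms:
            raise ValueError(
                f"{path}: frame has {n} atoms but topology has {topology.n_atoms}"
            )
        current = None
        for lineno, line in enumerate(fh, start=3):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "frame":
                if current is not None:
                    frames.append(Conformation(np.array(current)))
                times.append(float(parts[1]))
                current = []
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: coordinates before frame")
                current.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if current is not None:
            frames.append(Conformation(np.array(current)))
    return Trajectory(topology, frames, times, {"source": str(path)})


TABLE_SCHEMAS = {
    "noe": ["residue_i", "atom_i", "residue_j", "atom_j", "upper_nm"],
    "jcoupling": [
        "residue", "atoms", "coupling", "value_hz", "assignment_status", "cap_flag",
    ],
    "s2": ["residue", "atom_a", "atom_b", "value", "assignment_status"],
}


def read_table(path, kind: str):
    """Read a typed experimental/restraint table.

    Returns a list of :class:`NOERestraint` for ``kind='noe'``, otherwise a
    pandas DataFrame.  Schema violations raise with the offending column or
    row number.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for kind {kind!r}")
    if kind == "noe":
        out = []
        for row_no, row in df.iterrows():
            if row["upper_nm"] <= 0:
                raise ValueError(
                    f"{path}: row {row_no + 1}: non-positive NOE bound "
                    f"{row['upper_nm']}"
                )
            out.append(
                NOERestraint(
                    int(row["residue_i"]),
                    str(row["atom_i"]),
                    int(row["residue_j"]),
                    str(row["atom_j"]),
                    float(row["upper_nm"]),
                )
            )
        return out
    if kind == "jcoupling":
        bad = df[~df["coupling"].isin(["bb", "sc"])]
        if len(bad):
            raise ValueError(
                f"{path}: row {bad.index[0] + 1}: coupling must be 'bb' or 'sc'"
            )
    if kind == "s2":
        bad = df[(df["value"] < 0) | (df["value"] > 1)]
        if len(bad):
            raise ValueError(
                f"{path}: row {bad.index[0] + 1}: S2 outside [0, 1]"
            )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def parse_sd_config(path):
    """Parse a ``key = value`` config file into SDParameters; unknown keys
    are errors."""
    from .dynamics import SDParameters

    fields = {f.name: f.type for f in dataclasses.fields(SDParameters)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in ("thermostat_group",):
                kwargs[key] = val
            elif key in ("weak_coupling", "include_bonded_neighbours"):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key in ("rng_seed", "n_nbref"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
    return SDParameters(**kwargs)
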