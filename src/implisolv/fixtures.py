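"""Deterministic synthetic-input generators.

Every input class the package consumes — structures, trajectories, NOE
restraint sets and experimental 3J/S^2 tables — can be generated here so
the full pipeline runs with no external downloads.  Generators are
bitwise-reproducible under a seed.  The toy peptide chain uses idealised
bond lengths and angles (see ``IDEAL_GEOMETRY``); it emulates the shape of
protein input data, not any real protein's fold or measured values.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import Atom, Conformation, Topology, Trajectory, mass_for
from .observables import (
    NOERestraint,
    build_virtual_hydrogens,
    j_couplings_from_structure,
    karplus_extrema,
    load_corrections,
    noe_average_distance,
    resolve_atom_spec,
    s2_from_vectors,
    PARDI_BACKBONE,
    _bin_deviations,
    NOE_BIN_EDGES,
)

__all__ = [
    "IDEAL_GEOMETRY",
    "make_toy_chain",
    "make_cone_trajectory",
    "make_noe_fixture",
    "make_exp_tables",
    "wobble_in_cone_s2",
]

#: Idealised internal coordinates for the toy chain (nm / degrees).  Exact
#: values are uncritical; self-consistency with the constraint list is what
#: the generators guarantee.
IDEAL_GEOMETRY = {
    ("N", "CA"): 0.147,
    ("CA", "C"): 0.153,
    ("C", "N"): 0.133,
    ("C", "O"): 0.123,
    ("CA", "CB"): 0.153,
    "angle_C_N_CA": 121.0,
    "angle_N_CA_C": 111.0,
    "angle_CA_C_N": 116.0,
    "angle_CA_C_O": 121.0,
    "angle_N_CA_CB": 110.0,
    "omega": 180.0,
}


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(dih),
         bond * math.sin(ang) * math.sin(dih)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_toy_chain(
    n_residues: int, seed: int = 0, phi: float = -120.0, psi: float = 135.0
) -> tuple[Topology, Conformation]:
    """Backbone (N, CA, C, O) + CB chain with ideal geometry.

    CB alternates between a CH3 (odd residues; pseudo-site observables) and
    a prochiral CH2 group capped by a CG methyl (even residues; virtual
    H2/H3 pairs), so every virtual-site code path is exercised.  Backbone torsions take the given
    phi/psi with a small seeded jitter; all bond lengths equal their
    constraint-list targets exactly by construction.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    g = IDEAL_GEOMETRY
    coords: list[np.ndarray] = []
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []

    def add(name, element, code, resid, pos):
        atoms.append(
            Atom(name, element, mass_for(element, code), code, resid, "TOY")
        )
        coords.append(np.asarray(pos, dtype=float))
        return len(atoms) - 1

    idx: dict[tuple[int, str], int] = {}
    for r in range(1, n_residues + 1):
        jitter = rng.uniform(-10.0, 10.0, size=2)
        phi_r, psi_r = phi + jitter[0], psi + jitter[1]
        if r == 1:
            n_i = add("N", "N", "N", r, [0.0, 0.0, 0.0])
            ca_i = add(
                "CA", "C", "CH1", r, [g[("N", "CA")], 0.0, 0.0]
            )
            ang = math.radians(g["angle_N_CA_C"])
            c_pos = coords[ca_i] + g[("CA", "C")] * np.array(
                [-math.cos(ang), math.sin(ang), 0.0]
            )
            c_i = add("C", "C", "C", r, c_pos)
        else:
            prev_ca = idx[(r - 1, "CA")]
            prev_c = idx[(r - 1, "C")]
            n_pos = _place(
                coords[idx[(r - 1, "N")]],
                coords[prev_ca],
                coords[prev_c],
                g[("C", "N")],
                g["angle_CA_C_N"],
                psi_prev,
            )
            n_i = add("N", "N", "N", r, n_pos)
            ca_pos = _place(
                coords[prev_ca], coords[prev_c], coords[n_i],
                g[("N", "CA")], g["angle_C_N_CA"], g["omega"],
            )
            ca_i = add("CA", "C", "CH1", r, ca_pos)
            c_pos = _place(
                coords[prev_c], coords[n_i], coords[ca_i],
                g[("CA", "C")], g["angle_N_CA_C"], phi_r,
            )
            c_i = add("C", "C", "C", r, c_pos)
            bonds.append((prev_c, n_i))
        o_pos = _place(
            coords[n_i], coords[ca_i], coords[c_i],
            g[("C", "O")], g["angle_CA_C_O"], psi_r + 180.0,
        )
        o_i = add("O", "O", "O", r, o_pos)
        cb_code = "CH3" if r % 2 == 1 else "CH2"
        cb_pos = _place(
            coords[c_i], coords[n_i], coords[ca_i],
            g[("CA", "CB")], g["angle_N_CA_CB"], -122.0,
        )
        cb_i = add("CB", "C", cb_code, r, cb_pos)
        bonds.extend([(n_i, ca_i), (ca_i, c_i), (c_i, o_i), (ca_i, cb_i)])
        if cb_code == "CH2":  # cap the methylene so it has two heavy neighbours
            cg_pos = _place(
                coords[n_i], coords[ca_i], coords[cb_i],
                g[("CA", "CB")], 111.0, -60.0,
            )
            cg_i = add("CG", "C", "CH3", r, cg_pos)
            bonds.append((cb_i, cg_i))
            idx[(r, "CG")] = cg_i
        for nm, i in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i), ("CB", cb_i)):
            idx[(r, nm)] = i
        psi_prev = psi_r

    x = np.array(coords)
    constraints = [
        (i, j, float(np.linalg.norm(x[i] - x[j]))) for i, j in bonds
    ]
    topo = Topology(atoms, bonds, constraints)
    return topo, Conformation(x)


def wobble_in_cone_s2(half_angle_deg: float) -> float:
    """Closed-form S^2 for a vector uniformly distributed in a cone:
    S = cos(beta) (1 + cos(beta)) / 2, returned squared."""
    c = math.cos(math.radians(half_angle_deg))
    return (c * (1.0 + c) / 2.0) ** 2


def make_cone_trajectory(
    half_angle_deg: float, n_frames: int, seed: int = 0, bond: float = 0.1
) -> Trajectory:
    """Two-atom trajectory whose bond vector is uniform on the spherical
    cap of the given half-angle about +z (fixed bond length)."""
    if not (0.0 < half_angle_deg < 90.0):
        raise ValueError("half angle must be in (0, 90) degrees")
    rng = np.random.default_rng(seed)
    cmin = math.cos(math.radians(half_angle_deg))
    u = rng.uniform(cmin, 1.0, size=n_frames)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n_frames)
    s = np.sqrt(1.0 - u**2)
    dirs = np.stack([s * np.cos(phi), s * np.sin(phi), u], axis=1)
    atoms = [
        Atom("N", "N", mass_for("N", "N"), "N", 1, "TOY"),
        Atom("H", "H", mass_for("H", "H"), "H", 1, "TOY"),
    ]
    topo = Topology(atoms, bonds=[(0, 1)], constraints=[(0, 1, bond)])
    frames = [
        Conformation(np.array([[0.0, 0.0, 0.0], bond * d])) for d in dirs
    ]
    return Trajectory(topo, frames, [float(t) for t in range(n_frames)],
                      {"half_angle": half_angle_deg, "seed": seed})


def make_noe_fixture(
    topology: Topology,
    conf: Conformation,
    n_restraints: int,
    violation_sizes=(),
    seed: int = 0,
    margin: float = 0.05,
):
    """NOE restraint set on the given structure with planted violations.

    The first ``len(violation_sizes)`` restraints violate their (corrected)
    bound by exactly the stated amounts; the rest are satisfied with a
    ``margin``.  Returns (restraints, expected Table-3-style histogram).
    Wildcard/pseudo-site specs are included whenever the chosen proton site
    is a methyl pseudo-atom or a CH2 pair.
    """
    if n_restraints < len(violation_sizes):
        raise ValueError("more planted violations than restraints")
    rng = np.random.default_rng(seed)
    aug = build_virtual_hydrogens(conf, topology)
    corrections = load_corrections()
    # candidate proton sites: (residue, spec); CH2 pairs become one wildcard
    sites = []
    seen = set()
    for k in range(len(aug.names)):
        if not aug.is_virtual[k]:
            continue
        name = aug.names[k]
        res = int(aug.residue_indices[k])
        if name[-1] in "23" and name.startswith("HB"):
            spec = name[:-1] + "*"
        else:
            spec = name
        if (res, spec) not in seen:
            seen.add((res, spec))
            sites.append((res, spec))
    restraints = []
    violations = []
    attempts = 0
    while len(restraints) < n_restraints and attempts < 100 * n_restraints:
        attempts += 1
        pick = rng.choice(len(sites), size=2, replace=False)
        a, b = sites[int(pick[0])], sites[int(pick[1])]
        if a == b:
            continue
        mi = resolve_atom_spec(aug, a[0], a[1])
        mj = resolve_atom_spec(aug, b[0], b[1])
        if not mi or not mj:
            continue
        d = noe_average_distance([aug], mi, mj)
        from .observables import _side_correction

        corr = _side_correction(aug, mi, corrections) + _side_correction(
            aug, mj, corrections
        )
        k = len(restraints)
        v = violation_sizes[k] if k < len(violation_sizes) else 0.0
        bound = d - corr - v if v > 0 else d - corr + margin
        if bound <= 0.01:
            continue
        restraints.append(NOERestraint(a[0], a[1], b[0], b[1], bound))
        violations.append(v)
    if len(restraints) < n_restraints:
        raise RuntimeError("could not place the requested number of restraints")
    expected = _bin_deviations(violations, NOE_BIN_EDGES)
    return restraints, expected


def make_exp_tables(
    topology: Topology,
    traj_or_conf,
    noise: float = 0.0,
    seed: int = 0,
    unassigned_fraction: float = 0.3,
    s2_window_ps: float | None = None,
):
    """Synthetic experimental 3J and S^2 tables from a ground-truth
    structure or trajectory.

    Experimental values are the back-calculated truth plus Gaussian noise
    (sd ``noise``: Hz for 3J, absolute for S^2).  A fraction of the CH2
    side-chain coupling pairs is flagged stereo-specifically unassigned
    (``pair:<id>`` status, exp order randomised) so the assignment-recovery
    path runs; backbone values above the Karplus maximum are capped and
    flagged.  Returns (j_table, s2_table) DataFrames.
    """
    rng = np.random.default_rng(seed)
    residues = sorted(set(int(r) for r in topology.residue_indices))
    records = []
    for r in residues[1:]:  # residue 1 has no amide H (no preceding C)
        records.append({"residue": r, "atoms": "H-N-CA-HA", "coupling": "bb"})
    cb_is_ch2 = {
        a.residue_index
        for a in topology.atoms
        if a.name == "CB" and a.sasa_type == "CH2"
    }
    pair_ids = []
    for r in residues:
        if r in cb_is_ch2:
            records.append({"residue": r, "atoms": "HA-CA-CB-HB2", "coupling": "sc"})
            records.append({"residue": r, "atoms": "HA-CA-CB-HB3", "coupling": "sc"})
            pair_ids.append((len(records) - 2, len(records) - 1))

    calc, unresolved = j_couplings_from_structure(traj_or_conf, records, topology)
    if unresolved:
        raise RuntimeError(f"fixture generated unresolvable records: {unresolved}")
    exp = calc + noise * rng.standard_normal(len(calc))
    status = ["assigned"] * len(records)
    n_pairs_flagged = int(round(unassigned_fraction * len(pair_ids)))
    for pid, (i, j) in enumerate(pair_ids[:n_pairs_flagged]):
        status[i] = status[j] = f"pair:{pid}"
        if rng.random() < 0.5:  # randomise experimental order within the pair
            exp[i], exp[j] = exp[j], exp[i]
    jmax = karplus_extrema(PARDI_BACKBONE)[1]
    cap = np.zeros(len(records), dtype=int)
    for k, rec in enumerate(records):
        if rec["coupling"] == "bb" and exp[k] > jmax:
            exp[k] = jmax
            cap[k] = 1
    j_table = pd.DataFrame(
        {
            "residue": [r["residue"] for r in records],
            "atoms": [r["atoms"] for r in records],
            "coupling": [r["coupling"] for r in records],
            "value_hz": np.round(exp, 4),
            "assignment_status": status,
            "cap_flag": cap,
        }
    )

    # S^2 table over CA-CB vectors (real atoms, valid on any trajectory)
    s2_rows = []
    if isinstance(traj_or_conf, Trajectory) and len(traj_or_conf) >= 2:
        coords = traj_or_conf.coordinates
        for r in residues:
            ca = [i for i, a in enumerate(topology.atoms)
                  if a.residue_index == r and a.name == "CA"]
            cb = [i for i, a in enumerate(topology.atoms)
                  if a.residue_index == r and a.name == "CB"]
            if not ca or not cb:
                continue
            vecs = coords[:, ca[0], :] - coords[:, cb[0], :]
            truth = s2_from_vectors(vecs)
            s2_rows.append(
                {
                    "residue": r,
                    "atom_a": "CA",
                    "atom_b": "CB",
                    "value": float(np.clip(truth + noise * rng.standard_normal(), 0, 1)),
                    "assignment_status": "assigned",
                }
            )
    s2_table = pd.DataFrame(
        s2_rows, columns=["residue", "atom_a", "atom_b", "value", "assignment_status"]
    )
    return j_table, s2_table
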