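"""Minimal force field for exercising the dynamics engine.

Harmonic bonds and angles, cosine torsions, Lennard-Jones and Coulomb
non-bonded terms with a plain cutoff and first/second-neighbour exclusions,
plus optional hooks for the SASA solvation term and harmonic position
restraints.  This stands in for a full biomolecular force field so the
integrator, thermostat and constraint machinery can be driven end to end
on synthetic molecules; it is not a calibrated protein force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conformation, Topology

__all__ = ["ToyForceField", "toy_forcefield_eval"]

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_ELEC = 138.935458


@dataclass
class ToyForceField:
    """Bonded and non-bonded parameters referencing topology atom indices.

    bonds: (i, j, b0 nm, k kJ/mol/nm^2) with V = k/2 (r - b0)^2
    angles: (i, j, k, theta0 deg, k kJ/mol/rad^2) with V = k/2 (theta - theta0)^2
    torsions: (i, j, k, l, multiplicity, phase deg, k kJ/mol)
              with V = k (1 + cos(m*phi - phase))
    lj: per-atom (c6, c12) in kJ/mol nm^6 and kJ/mol nm^12, combined
        geometrically; charges in e; eps_r relative permittivity.
    exclusions: atom pairs excluded from non-bonded terms (normally all
        first and second covalent neighbours).
    """

    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    c6: np.ndarray | None = None
    c12: np.ndarray | None = None
    charges: np.ndarray | None = None
    eps_r: float = 1.0
    cutoff: float = 1.4
    exclusions: set = field(default_factory=set)

    @classmethod
    def from_topology(
        cls, topology: Topology, k_bond=400000.0, k_angle=400.0, **kwargs
    ) -> "ToyForceField":
        """Harmonic bonded terms at the topology's current idealised
        geometry targets; non-bonded pairs exclude 1-2 and 1-3 neighbours."""
        bonds = [(i, j, d, k_bond) for i, j, d in topology.constraints] or [
            (i, j, 0.15, k_bond) for i, j in topology.bonds
        ]
        adj = topology.bonded_neighbours()
        angles = []
        for j in range(topology.n_atoms):
            nbrs = sorted(adj[j])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    angles.append((nbrs[a], j, nbrs[b], 109.5, k_angle))
        excl = set()
        n = topology.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if topology.neighbour_order(i, j) <= 2:
                    excl.add((i, j))
        return cls(bonds=bonds, angles=angles, exclusions=excl, **kwargs)


def _bond_terms(x, ff, forces):
    e = 0.0
    for i, j, b0, k in ff.bonds:
        d = x[i] - x[j]
        r = np.linalg.norm(d)
        e += 0.5 * k * (r - b0) ** 2
        f = -k * (r - b0) * d / r
        forces[i] += f
        forces[j] -= f
    return e


def _angle_terms(x, ff, forces):
    e = 0.0
    for i, j, k, th0_deg, kt in ff.angles:
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos_t = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        th0 = np.deg2rad(th0_deg)
        e += 0.5 * kt * (theta - th0) ** 2
        sin_t = max(np.sqrt(1.0 - cos_t**2), 1e-10)
        dvdt = kt * (theta - th0)
        fi = -dvdt * (cos_t * u / nu - v / nv) / (nu * sin_t)
        fk = -dvdt * (cos_t * v / nv - u / nu) / (nv * sin_t)
        forces[i] += fi
        forces[k] += fk
        forces[j] -= fi + fk
    return e


def dihedral_angle(x, i, j, k, l) -> float:
    """Torsion angle in radians for atoms i-j-k-l, in (-pi, pi]."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


def _torsion_terms(x, ff, forces):
    e = 0.0
    for i, j, k, l, mult, phase_deg, kphi in ff.torsions:
        b1 = x[j] - x[i]
        b2 = x[k] - x[j]
        b3 = x[l] - x[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        phi = np.arctan2(np.cross(n1, b2 / nb2) @ n2, n1 @ n2)
        phase = np.deg2rad(phase_deg)
        e += kphi * (1.0 + np.cos(mult * phi - phase))
        dvdphi = -kphi * mult * np.sin(mult * phi - phase)
        # exact dihedral gradient (Blondel-Karplus form, our sign convention)
        sq1 = n1 @ n1
        sq2 = n2 @ n2
        t1 = (b1 @ b2) / (sq1 * nb2)
        t2 = (b3 @ b2) / (sq2 * nb2)
        dphi_di = (nb2 / sq1) * n1
        dphi_dl = -(nb2 / sq2) * n2
        dphi_dj = -dphi_di - t1 * n1 - t2 * n2
        dphi_dk = -dphi_dl + t1 * n1 + t2 * n2
        forces[i] -= dvdphi * dphi_di
        forces[j] -= dvdphi * dphi_dj
        forces[k] -= dvdphi * dphi_dk
        forces[l] -= dvdphi * dphi_dl
    return e


def _nonbonded_terms(x, ff, forces):
    n = len(x)
    e_lj = e_coul = 0.0
    has_lj = ff.c6 is not None and ff.c12 is not None
    has_q = ff.charges is not None
    if not (has_lj or has_q):
        return 0.0, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in ff.exclusions or (j, i) in ff.exclusions:
                continue
            d = x[i] - x[j]
            r = np.linalg.norm(d)
            if r >= ff.cutoff:
                continue
            if r < 1e-6:
                raise ValueError(f"overlapping non-bonded atoms {i}, {j}")
            fmag = 0.0
            if has_lj:
                c6 = np.sqrt(ff.c6[i] * ff.c6[j])
                c12 = np.sqrt(ff.c12[i] * ff.c12[j])
                e_lj += c12 / r**12 - c6 / r**6
                fmag += (12.0 * c12 / r**13 - 6.0 * c6 / r**7)
            if has_q:
                qq = F_ELEC * ff.charges[i] * ff.charges[j] / ff.eps_r
                e_coul += qq / r
                fmag += qq / r**2
            f = fmag * d / r
            forces[i] += f
            forces[j] -= f
    return e_lj, e_coul


def toy_forcefield_eval(conf: Conformation, ff: ToyForceField):
    """Per-term energies (kJ/mol) and total analytic forces (kJ/mol/nm)."""
    x = conf.coordinates
    forces = np.zeros_like(x)
    energies = {}
    energies["bond"] = _bond_terms(x, ff, forces)
    energies["angle"] = _angle_terms(x, ff, forces)
    energies["torsion"] = _torsion_terms(x, ff, forces)
    e_lj, e_coul = _nonbonded_terms(x, ff, forces)
    energies["lj"] = e_lj
    energies["coulomb"] = e_coul
    return energies, forces
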