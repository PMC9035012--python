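"""SASA implicit-solvation energy and analytical forces.

The mean solvation energy is modelled as proportional to the
solvent-accessible surface area of each atom,

    V_solv = sum_i sigma_i * A_i,

with the per-atom accessible area approximated by the Hasel product formula

    A_i = S_i * prod_j [1 - p_i * p_ij * b_ij(r_ij) / S_i],

where S_i = 4*pi*(R_i + R_solv)^2 is the area of the isolated atom, b_ij is
the pairwise overlap reduction factor and p_i, p_ij are empirical
double-counting corrections (p_ij distinguishes first and second covalent
neighbours).  Forces are the exact analytical gradient of this expression.

Product factors are clamped to [0, 1] (with zero derivative where clamped)
to prevent sign-flipping areas at unphysically short distances; clamping
events are reported on the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .core import Conformation, Topology

__all__ = [
    "SASAParameterSet",
    "SASAResult",
    "load_parameter_set",
    "isolated_area",
    "overlap_reduction",
    "overlap_reduction_derivative",
    "atomic_areas",
    "sasa_energy_forces",
    "classify_areas",
]

#: Probe radius of the water-like solvent atom (nm).
R_SOLV = 0.14
#: Pair reduction factor for covalently bound first neighbours.
P_FIRST = 0.8875
#: Pair reduction factor for covalently bound second neighbours.
P_NEXT = 0.3516

_HYDROPHILIC_TYPES = frozenset(
    {"O", "OM", "OA", "OE", "N", "NT", "NL", "NR", "NZ", "NE"}
)
_HYDROPHOBIC_TYPES = frozenset({"C", "CH0", "CH1", "CH2", "CH2r", "CH3", "CR1"})


@dataclass(frozen=True)
class SASAParameterSet:
    """Per-type radii, overlap parameters and surface-energy coefficients.

    ``set_id`` selects the surface-energy column: ``"per-type"`` (one sigma
    per atom type) or ``"three-class"`` (one sigma per polar / charged /
    hydrophobic class).  Types without a radius (OW, CH4, DUM) take part in
    neither area nor occlusion; types with a radius but no sigma raise when
    the energy term is requested, unless an override sigma is supplied.
    """

    radii: dict
    p_i: dict
    sigma: dict
    set_id: str
    r_solv: float = R_SOLV
    p_first: float = P_FIRST
    p_next: float = P_NEXT
    sigma_overrides: dict = field(default_factory=dict)

    def has_radius(self, code: str) -> bool:
        return not math.isnan(self.radii.get(code, math.nan))

    def radius(self, code: str) -> float:
        r = self.radii.get(code, math.nan)
        if math.isnan(r):
            raise ValueError(f"atom type {code!r} has no defined radius")
        return r

    def sigma_for(self, code: str) -> float:
        if code in self.sigma_overrides:
            return self.sigma_overrides[code]
        s = self.sigma.get(code, math.nan)
        if math.isnan(s):
            raise ValueError(
                f"atom type {code!r} has no sigma in the {self.set_id!r} "
                "parameter set; supply sigma_overrides to use it"
            )
        return s

    def pair_factor(self, order: int) -> float:
        """p_ij for covalent separation ``order`` (1, 2, or >=3)."""
        if order == 1:
            return self.p_first
        if order == 2:
            return self.p_next
        return 1.0


def load_parameter_set(set_id: str = "per-type", **kwargs) -> SASAParameterSet:
    """Load one of the two packaged parameter sets.

    The three-class set assigns no class to the sigma-zero types (HC, H, S);
    these inherit sigma = 0 so that hydrogen- or sulphur-containing solutes
    remain usable with either set.
    """
    if set_id not in ("per-type", "three-class"):
        raise ValueError(f"unknown parameter set {set_id!r}")
    path = resources.files("implisolv.data").joinpath("sasa_params.tsv")
    radii, p_i, sig_t, sig_c = {}, {}, {}, {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("code\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                continue
            _, name, r, p, st, _, sc, _ = parts
            radii[name] = float(r) if r != "-" else math.nan
            p_i[name] = float(p) if p != "-" else math.nan
            sig_t[name] = float(st) if st != "-" else math.nan
            if sc != "-":
                sig_c[name] = float(sc)
            elif st != "-" and float(st) == 0.0:
                sig_c[name] = 0.0
            else:
                sig_c[name] = math.nan
    sigma = sig_t if set_id == "per-type" else sig_c
    return SASAParameterSet(radii=radii, p_i=p_i, sigma=sigma, set_id=set_id, **kwargs)


@dataclass
class SASAResult:
    """Areas, solvation energy and forces for one conformation.

    ``areas`` and ``isolated`` are NaN for atoms excluded from the model
    (no defined radius).  ``clamped_pairs`` lists (i, j) pairs whose product
    factor was clamped, as a model-deviation flag.
    """

    areas: np.ndarray
    isolated: np.ndarray
    energy: float
    forces: np.ndarray
    hydrophilic: float
    hydrophobic: float
    total: float
    excluded: list
    clamped_pairs: list


def isolated_area(type_code: str, params: SASAParameterSet) -> float:
    """Surface area 4*pi*(R_i + R_solv)^2 of the isolated atom (nm^2)."""
    r = params.radius(type_code)
    return 4.0 * math.pi * (r + params.r_solv) ** 2


def overlap_reduction(
    r_ij: float, type_i: str, type_j: str, params: SASAParameterSet
) -> float:
    """Overlap reduction b_ij of atom i's sphere by atom j (nm^2).

    Note the asymmetry: b_ij quantifies the area removed from atom *i*.
    Zero at and beyond the contact cutoff R_i + R_j + 2*R_solv.
    """
    if r_ij <= 0:
        raise ValueError("coincident atoms: r_ij must be > 0")
    ri, rj = params.radius(type_i), params.radius(type_j)
    cutoff = ri + rj + 2.0 * params.r_solv
    if r_ij >= cutoff:
        return 0.0
    return math.pi * (ri + params.r_solv) * (cutoff - r_ij) * (1.0 + (rj - ri) / r_ij)


def overlap_reduction_derivative(
    r_ij: float, type_i: str, type_j: str, params: SASAParameterSet
) -> float:
    """d b_ij / d r_ij (nm)."""
    if r_ij <= 0:
        raise ValueError("coincident atoms: r_ij must be > 0")
    ri, rj = params.radius(type_i), params.radius(type_j)
    cutoff = ri + rj + 2.0 * params.r_solv
    if r_ij >= cutoff:
        return 0.0
    a = math.pi * (ri + params.r_solv)
    return -a * (1.0 + (rj - ri) / r_ij) + a * (-(rj - ri) / r_ij**2) * (
        cutoff - r_ij
    )


def _pair_tables(topology: Topology, params: SASAParameterSet, hydrogens_occlude):
    """Per-atom radius/p/S arrays; NaN radius marks exclusion."""
    n = topology.n_atoms
    radii = np.full(n, np.nan)
    p = np.full(n, np.nan)
    for k, code in enumerate(topology.sasa_types):
        if not params.has_radius(code):
            continue
        if topology.is_hydrogen(k) and not hydrogens_occlude:
            continue
        radii[k] = params.radii[code]
        p[k] = params.p_i[code]
    s = 4.0 * math.pi * (radii + params.r_solv) ** 2
    return radii, p, s


def _pairwise(conf, topology, params, hydrogens_occlude):
    """All geometry- and parameter-dependent pair quantities within cutoff.

    Returns per-atom tables and, per unordered pair (i < j) in range:
    indices, distances, unit vectors i->j, clamped product factors for both
    orientations and the (derivative-carrying) b' values.
    """
    radii, p, s = _pair_tables(topology, params, hydrogens_occlude)
    x = conf.coordinates
    active = np.flatnonzero(~np.isnan(radii))
    if len(active) < 2:
        empty = np.empty((0,))
        return radii, p, s, active, np.empty((0, 2), dtype=int), empty, np.empty((0, 3))
    rmax = np.nanmax(radii)
    cutoff = 2.0 * rmax + 2.0 * params.r_solv
    tree = cKDTree(x[active])
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    pairs = active[raw]
    if len(pairs):
        d = x[pairs[:, 1]] - x[pairs[:, 0]]
        r = np.linalg.norm(d, axis=1)
        if np.any(r <= 1e-12):
            bad = pairs[r <= 1e-12][0]
            raise ValueError(f"overlapping atoms {bad[0]} and {bad[1]} at r = 0")
        u = d / r[:, None]
        within = r < radii[pairs[:, 0]] + radii[pairs[:, 1]] + 2.0 * params.r_solv
        pairs, r, u = pairs[within], r[within], u[within]
    else:
        r = np.empty((0,))
        u = np.empty((0, 3))
    return radii, p, s, active, pairs, r, u


def _factors(pairs, r, radii, p, s, topology, params):
    """Clamped Hasel product factors and derivative scalars for both pair
    orientations: (i occluded by j) and (j occluded by i)."""
    m = len(pairs)
    f = np.ones((m, 2))
    dscal = np.zeros((m, 2))  # p_i * p_ij * db/dr, zeroed where clamped
    clamped = []
    p_ij = np.array(
        [params.pair_factor(topology.neighbour_order(i, j)) for i, j in pairs]
    )
    for side in (0, 1):
        i = pairs[:, side]
        j = pairs[:, 1 - side]
        ri, rj = radii[i], radii[j]
        a = math.pi * (ri + params.r_solv)
        cutoff = ri + rj + 2.0 * params.r_solv
        b = a * (cutoff - r) * (1.0 + (rj - ri) / r)
        db = -a * (1.0 + (rj - ri) / r) + a * (-(rj - ri) / r**2) * (cutoff - r)
        raw = 1.0 - p[i] * p_ij * b / s[i]
        clamp = (raw <= 0.0) | (raw >= 1.0)
        f[:, side] = np.clip(raw, 0.0, 1.0)
        dscal[:, side] = np.where(clamp, 0.0, p[i] * p_ij * db)
        for k in np.flatnonzero(raw <= 0.0):
            clamped.append((int(i[k]), int(j[k])))
    return f, dscal, clamped


def atomic_areas(
    conf: Conformation,
    topology: Topology,
    params: SASAParameterSet,
    hydrogens_occlude: bool = True,
) -> np.ndarray:
    """Per-atom accessible areas A_i (nm^2); NaN for excluded atoms."""
    radii, p, s, active, pairs, r, u = _pairwise(
        conf, topology, params, hydrogens_occlude
    )
    f, _, _ = _factors(pairs, r, radii, p, s, topology, params) if len(pairs) else (
        np.empty((0, 2)),
        None,
        None,
    )
    prod = np.ones(topology.n_atoms)
    if len(pairs):
        np.multiply.at(prod, pairs[:, 0], f[:, 0])
        np.multiply.at(prod, pairs[:, 1], f[:, 1])
    areas = s * prod
    return areas


def sasa_energy_forces(
    conf: Conformation,
    topology: Topology,
    params: SASAParameterSet,
    hydrogens_occlude: bool = True,
) -> SASAResult:
    """Solvation energy (kJ/mol) and analytical forces (kJ/mol/nm).

    Forces come from the exact gradient of the clamped product expression;
    each pair contributes equal and opposite forces, so the net force and
    torque vanish identically.
    """
    radii, p, s, active, pairs, r, u = _pairwise(
        conf, topology, params, hydrogens_occlude
    )
    n = topology.n_atoms
    sigma = np.zeros(n)
    for k in active:
        sigma[k] = params.sigma_for(topology.sasa_types[k])

    prod = np.ones(n)
    nzero = np.zeros(n, dtype=int)
    clamped: list = []
    if len(pairs):
        f, dscal, clamped = _factors(pairs, r, radii, p, s, topology, params)
        np.multiply.at(prod, pairs[:, 0], f[:, 0])
        np.multiply.at(prod, pairs[:, 1], f[:, 1])
        zero0 = f[:, 0] == 0.0
        zero1 = f[:, 1] == 0.0
        np.add.at(nzero, pairs[:, 0][zero0], 1)
        np.add.at(nzero, pairs[:, 1][zero1], 1)

    areas = s * prod
    defined = ~np.isnan(areas)
    energy = float(np.sum(sigma[defined] * areas[defined]))

    forces = np.zeros((n, 3))
    if len(pairs):
        # product over all partners of i except k; zero if any other factor is 0
        def excl(side):
            i = pairs[:, side]
            fi = f[:, side]
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(fi > 0.0, prod[i] / np.where(fi > 0, fi, 1.0), 0.0)
            out = np.where(nzero[i] > 0, 0.0, out)
            return out

        # c = p_i * p_ij * b'_ij * prod_{l != j} factor_il  for each orientation
        c0 = dscal[:, 0] * excl(0)  # area of atom pairs[:,0] occluded by pairs[:,1]
        c1 = dscal[:, 1] * excl(1)
        i, j = pairs[:, 0], pairs[:, 1]
        # dV/dr_j from A_i term: -sigma_i * c0 * u_ij ; force is the negative
        g = (sigma[i] * c0 + sigma[j] * c1)[:, None] * u  # u points i -> j
        # dA_i/dr_i = +c0 * (-u); dA_i/dr_j = +c0 * (+u) with u_hat = dr/dr_j
        np.add.at(forces, j, g)
        np.add.at(forces, i, -g)

    hydphil, hydphob, total = _class_sums(areas, topology)
    return SASAResult(
        areas=areas,
        isolated=s,
        energy=energy,
        forces=forces,
        hydrophilic=hydphil,
        hydrophobic=hydphob,
        total=total,
        excluded=[int(k) for k in np.flatnonzero(np.isnan(radii))],
        clamped_pairs=clamped,
    )


def _class_sums(areas: np.ndarray, topology: Topology):
    hydphil = hydphob = total = 0.0
    for k, code in enumerate(topology.sasa_types):
        a = areas[k]
        if math.isnan(a):
            continue
        total += a
        if code in _HYDROPHILIC_TYPES:
            hydphil += a
        elif code in _HYDROPHOBIC_TYPES:
            hydphob += a
    return hydphil, hydphob, total


def classify_areas(result: SASAResult, topology: Topology):
    """(hydrophilic, hydrophobic, total) area sums in nm^2.

    Hydrophilic covers the nitrogen and oxygen types, hydrophobic the carbon
    types; the total also counts sulphur and hydrogen surfaces.
    """
    return _class_sums(result.areas, topology)
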