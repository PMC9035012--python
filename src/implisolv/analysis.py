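"""Geometric trajectory analyses.

Superposition uses the Kabsch least-squares fit (proper rotations only);
RMSD/RMSF and S^2 calculations rely on it to remove overall translation
and rotation before measuring internal motion.  Autocorrelation functions
follow C_Q(t) = <Q(tau)·Q(tau+t)>_tau / <Q(tau)·Q(tau)>_tau, evaluated via
FFT; spectral densities use only the leading fraction (default 2%) of the
correlation function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Conformation, Topology, Trajectory, center_of_mass
from .forcefield import dihedral_angle
from .observables import build_virtual_hydrogens

__all__ = [
    "SuperpositionResult",
    "HBondCriterion",
    "TimeSeries",
    "superimpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "hydrogen_bonds",
    "hydrogen_bond_extent",
    "autocorrelation",
    "spectral_density",
    "torsion_series",
]

#: Acceptor SASA type codes (N- and O-class heavy atoms).
ACCEPTOR_TYPES = frozenset({"N", "NT", "NL", "NR", "NZ", "NE", "O", "OM", "OA", "OE"})


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), proper
    translation: np.ndarray  # nm
    rmsd: float  # nm, over the fit selection
    selection: list


@dataclass(frozen=True)
class HBondCriterion:
    """A hydrogen bond exists if the H-acceptor distance is < ``max_ha``
    and the donor-H-acceptor angle is > ``min_angle`` (both strict)."""

    max_ha: float = 0.25  # nm
    min_angle: float = 135.0  # degrees

    def __post_init__(self):
        if self.max_ha <= 0 or not (0.0 < self.min_angle < 180.0):
            raise ValueError("invalid hydrogen-bond criterion")


@dataclass
class TimeSeries:
    """Uniformly sampled scalar or fixed-dimension vector series."""

    values: np.ndarray
    dt: float  # ps

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")


def superimpose(ref: np.ndarray, mobile: np.ndarray, selection=None):
    """Kabsch fit of ``mobile`` onto ``ref`` over ``selection`` atoms.

    Returns the :class:`SuperpositionResult` and all mobile coordinates
    moved into the reference frame.  Reflections are excluded: the returned
    rotation always has determinant +1.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if selection is None:
        selection = list(range(len(ref)))
    sel = list(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms to superimpose")
    a = ref[sel]
    b = mob[sel]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:  # rank < 2: collinear selection
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted_sel = (rot @ b0.T).T + ca
    rmsd = float(np.sqrt(np.mean(np.sum((fitted_sel - a) ** 2, axis=1))))
    moved = (rot @ (mob - cb).T).T + ca
    return SuperpositionResult(rot, ca - rot @ cb, rmsd, sel), moved


def rmsd_series(traj: Trajectory, ref: np.ndarray, selection, fit_selection=None):
    """Per-frame RMSD (nm) versus a reference after per-frame superposition.

    ``fit_selection`` (default: same as ``selection``) chooses the atoms of
    the rigid-body fit; ``selection`` the atoms entering the RMSD.
    """
    if fit_selection is None:
        fit_selection = selection
    out = []
    for f in traj.frames:
        _, moved = superimpose(ref, f.coordinates, fit_selection)
        d = moved[selection] - np.asarray(ref)[selection]
        out.append(float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return np.array(out)


def rmsf(traj: Trajectory, selection, fit_selection=None):
    """Per-atom rms fluctuation (nm) about the trajectory-average position,
    after fitting every frame onto the first."""
    if fit_selection is None:
        fit_selection = selection
    ref = traj.frames[0].coordinates
    fitted = []
    for f in traj.frames:
        _, moved = superimpose(ref, f.coordinates, fit_selection)
        fitted.append(moved[selection])
    arr = np.array(fitted)  # (n_frames, n_sel, 3)
    mean = arr.mean(axis=0)
    return np.sqrt(np.mean(np.sum((arr - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(
    conf: Conformation, topology: Topology, normalized: bool = True
) -> float:
    """Mass-weighted rms distance from the centre of mass (nm).

    With ``normalized=False`` the raw (un-normalised) root of the summed
    squared distances is returned instead of the standard definition."""
    m = topology.masses
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    com = center_of_mass(conf, topology)
    d2 = np.sum((conf.coordinates - com) ** 2, axis=1)
    if not normalized:
        return float(np.sqrt(np.sum(d2)))
    return float(np.sqrt(np.sum(m * d2) / m.sum()))


def _donors_acceptors(topology: Topology, aug):
    """Donor (D, H) pairs and acceptor indices on the augmented frame.

    Donors are N/O heavy atoms with an attached explicit or virtual H
    (pseudo methyl sites never donate); acceptors are N/O heavy atoms."""
    donors = []
    acceptors = []
    n_real = topology.n_atoms
    adj = topology.bonded_neighbours()
    for i, atom in enumerate(topology.atoms):
        if atom.sasa_type in ACCEPTOR_TYPES:
            acceptors.append(i)
            for j in adj[i]:
                if topology.is_hydrogen(j):
                    donors.append((i, j))
    # virtual hydrogens: attach to their heavy atom by proximity of record order
    for k in range(n_real, len(aug.names)):
        if aug.is_pseudo[k] or not aug.names[k].startswith("H"):
            continue
        # virtual H on a nitrogen: name 'H' + stem built from the N name
        res = aug.residue_indices[k]
        name = aug.names[k]
        for i, atom in enumerate(topology.atoms):
            if (
                atom.residue_index == res
                and atom.sasa_type in ACCEPTOR_TYPES
                and atom.element == "N"
                and ("H" + atom.name[1:]) == name
            ):
                donors.append((i, k))
    return donors, acceptors


def hydrogen_bonds(
    traj_or_conf,
    topology: Topology,
    criterion: HBondCriterion = HBondCriterion(),
):
    """Detect intra-solute hydrogen bonds; returns ``{(donor, H-name,
    acceptor): occupancy}`` with occupancy as the fraction of frames."""
    frames = (
        traj_or_conf.frames
        if isinstance(traj_or_conf, Trajectory)
        else [traj_or_conf]
    )
    counts: dict = {}
    n_frames = len(frames)
    for conf in frames:
        aug = build_virtual_hydrogens(conf, topology)
        donors, acceptors = _donors_acceptors(topology, aug)
        x = aug.coordinates
        for d_idx, h_idx in donors:
            for a_idx in acceptors:
                if a_idx == d_idx:
                    continue
                ha = x[a_idx] - x[h_idx]
                dist = np.linalg.norm(ha)
                if dist >= criterion.max_ha:
                    continue
                hd = x[d_idx] - x[h_idx]
                cosang = (hd @ ha) / (np.linalg.norm(hd) * dist)
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if ang <= criterion.min_angle:
                    continue
                key = (d_idx, aug.names[h_idx], a_idx)
                counts[key] = counts.get(key, 0) + 1
    return {k: v / n_frames for k, v in counts.items()}


def hydrogen_bond_extent(occupancies: dict, reference_count: int) -> float:
    """Hydrogen-bonding extent: summed occupancies relative to the number
    of hydrogen bonds in a reference structure (1.0 = 100%)."""
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return sum(occupancies.values()) / reference_count


def autocorrelation(series: TimeSeries) -> TimeSeries:
    """Normalised autocorrelation via FFT, C(0) = 1.

    Vector-valued series use the dot product; the estimate at lag t divides
    by the number of contributing pairs (n - t)."""
    q = series.values
    if q.ndim == 1:
        q = q[:, None]
    n = len(q)
    if n < 2:
        raise ValueError("correlation needs a series of length >= 2")
    norm = float(np.mean(np.einsum("ij,ij->i", q, q)))
    if norm == 0.0:
        raise ValueError("all-zero series: normalisation undefined")
    nfft = 1 << (2 * n - 1).bit_length()
    acc = np.zeros(n)
    for d in range(q.shape[1]):
        f = np.fft.rfft(q[:, d], nfft)
        acc += np.fft.irfft(f * np.conj(f), nfft)[:n]
    c = acc / (n - np.arange(n)) / norm
    return TimeSeries(c, series.dt)


def autocorrelation_direct(series: TimeSeries) -> TimeSeries:
    """O(n^2) reference evaluation of the same estimator (test oracle)."""
    q = series.values
    if q.ndim == 1:
        q = q[:, None]
    n = len(q)
    norm = float(np.mean(np.einsum("ij,ij->i", q, q)))
    if norm == 0.0:
        raise ValueError("all-zero series: normalisation undefined")
    c = np.empty(n)
    for lag in range(n):
        c[lag] = np.mean(
            np.einsum("ij,ij->i", q[: n - lag], q[lag:])
        ) / norm
    return TimeSeries(c, series.dt)


def spectral_density(corr: TimeSeries, fraction: float = 0.02):
    """Spectral density from the leading ``fraction`` of C(t).

    Returns (angular frequency in ps^-1, density) from the cosine transform
    of the truncated correlation function."""
    n_keep = max(int(round(fraction * len(corr.values))), 2)
    c = corr.values[:n_keep]
    spec = np.fft.rfft(c).real * corr.dt
    freq = 2.0 * math.pi * np.fft.rfftfreq(n_keep, corr.dt)
    return freq, spec


def torsion_series(traj: Trajectory, atoms: tuple[int, int, int, int]) -> TimeSeries:
    """Per-frame torsion embedded as the unit vector (cos chi, sin chi).

    The embedding makes the autocorrelation dot product periodic-safe and
    yields C(0) = 1 automatically; the raw angles (degrees) are stored on
    the series as ``angles``."""
    i, j, k, l = atoms
    angs = []
    for f in traj.frames:
        angs.append(dihedral_angle(f.coordinates, i, j, k, l))
    angs = np.array(angs)
    values = np.stack([np.cos(angs), np.sin(angs)], axis=1)
    dt = traj.times[1] - traj.times[0] if len(traj) > 1 else 1.0
    ts = TimeSeries(values, dt)
    ts.angles = np.degrees(angs)
    return ts
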