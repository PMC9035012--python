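"""Back-calculation of NMR observables and deviation scoring.

United-atom models carry no aliphatic hydrogens, so inter-proton NOE
distances and H-involving dihedrals are evaluated on virtual atomic
positions (CH, prochiral CH2) and pseudo-atomic positions (CH3, placed at
the methyl carbon with a compensating distance-bound correction).

Observables covered:

* NOE distances with r^-3 trajectory averaging, wildcard/pseudo-atom
  resolution and Wuethrich-style bound corrections; violations binned as
  0.05-0.1 / 0.1-0.15 / 0.15-0.2 / 0.2-0.25 / 0.25-0.3 / >0.3 nm.
* 3J couplings via the Karplus relation J = a cos^2(theta) + b cos(theta)
  + c, measured directly on the H-N-CA-HA (backbone, Pardi parameters) or
  HA-CA-CB-HB (side chain, DeMarco parameters) dihedral; deviations binned
  as 1-2 / 2-3 / 3-4 / 4-5 / >5 Hz.
* S^2 order parameters from the ensemble-averaging expression over
  non-overlapping time windows; deviations binned as 0.05-0.1 / 0.1-0.2 /
  0.2-0.3 / 0.3-0.4 / 0.4-0.5 / >0.5.

Deviations below 0.1 nm (NOE), 2 Hz (3J) and 0.2 (S^2) are considered
insignificant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import Conformation, Topology, Trajectory

__all__ = [
    "AugmentedConformation",
    "NOERestraint",
    "KarplusParameters",
    "PARDI_BACKBONE",
    "DEMARCO_SIDECHAIN",
    "DeviationReport",
    "NOE_BIN_EDGES",
    "J_BIN_EDGES",
    "S2_BIN_EDGES",
    "SIGNIFICANCE",
    "load_corrections",
    "build_virtual_hydrogens",
    "resolve_atom_spec",
    "noe_average_distance",
    "noe_violation_report",
    "karplus_j",
    "karplus_extrema",
    "j_couplings_from_structure",
    "resolve_ambiguous_assignment",
    "s2_from_vectors",
    "order_parameter",
    "deviation_histograms",
]

#: Histogram bin edges; the last bin is open-ended.
NOE_BIN_EDGES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
J_BIN_EDGES = (1.0, 2.0, 3.0, 4.0, 5.0)
S2_BIN_EDGES = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

#: Deviations below these are considered insignificant.
SIGNIFICANCE = {"noe": 0.1, "J": 2.0, "S2": 0.2}

#: C-H distance for virtual-site construction (nm).
CH_BOND = 0.10
#: N-H distance for planar amide construction (nm).
NH_BOND = 0.10
#: Half the tetrahedral angle, for prochiral CH2 construction.
_TET_HALF = math.radians(109.47 / 2.0)


def load_corrections() -> dict:
    """Pseudo-atom NOE bound corrections (nm) from package data."""
    path = resources.files("implisolv.data").joinpath("pseudoatom_corrections.tsv")
    out = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("kind"):
                continue
            kind, val = line.split()
            out[kind] = float(val)
    return out


# ---------------------------------------------------------------------------
# virtual / pseudo hydrogen construction


@dataclass
class AugmentedConformation:
    """Real atoms plus virtual/pseudo hydrogen sites for one frame."""

    coordinates: np.ndarray
    names: list
    residue_indices: np.ndarray
    is_virtual: np.ndarray
    is_pseudo: np.ndarray  # CH3 pseudo-sites (and any multi-proton site)

    def find(self, residue: int, name: str) -> int:
        for k in range(len(self.names)):
            if self.residue_indices[k] == residue and self.names[k] == name:
                return k
        raise KeyError(f"atom {name!r} in residue {residue} not found")


def _h_stem(heavy_name: str) -> str:
    """HA from CA, HB from CB, HG1 from CG1, H from N."""
    return "H" + heavy_name[1:]


def build_virtual_hydrogens(
    conf: Conformation, topology: Topology
) -> AugmentedConformation:
    """Construct hydrogen positions a united-atom model leaves implicit.

    CH groups get one virtual H on the negative resultant of the three
    heavy-neighbour unit vectors; prochiral CH2 groups get an H2/H3 pair
    mirror-symmetric about the heavy-neighbour plane (H2 on the positive
    side of u1 x u2, with neighbours ordered by atom index); CH3 groups get
    a single pseudo-site at the carbon named with a trailing ``*``; peptide
    nitrogens without an explicit H get a planar amide H.
    """
    x = conf.coordinates
    adj = topology.bonded_neighbours()
    coords = [x[i] for i in range(topology.n_atoms)]
    names = list(topology.names)
    resids = list(topology.residue_indices)
    virt = [False] * topology.n_atoms
    pseudo = [False] * topology.n_atoms

    def unit_to(i, j):
        d = x[j] - x[i]
        return d / np.linalg.norm(d)

    for i, atom in enumerate(topology.atoms):
        code = atom.sasa_type
        nbrs = sorted(adj[i])
        site = f"{atom.residue_name} {atom.residue_index} {atom.name}"
        if code == "CH1":
            if len(nbrs) < 3:
                raise ValueError(f"CH site {site} needs 3 heavy neighbours")
            s = sum(unit_to(i, j) for j in nbrs[:3])
            h = x[i] - CH_BOND * s / np.linalg.norm(s)
            coords.append(h)
            names.append(_h_stem(atom.name))
            resids.append(atom.residue_index)
            virt.append(True)
            pseudo.append(False)
        elif code in ("CH2", "CH2r"):
            if len(nbrs) < 2:
                raise ValueError(f"CH2 site {site} needs 2 heavy neighbours")
            u1, u2 = unit_to(i, nbrs[0]), unit_to(i, nbrs[1])
            bis = -(u1 + u2)
            bis /= np.linalg.norm(bis)
            n = np.cross(u1, u2)
            n /= np.linalg.norm(n)
            stem = _h_stem(atom.name)
            for suffix, sign in (("2", 1.0), ("3", -1.0)):
                h = x[i] + CH_BOND * (
                    math.cos(_TET_HALF) * bis + sign * math.sin(_TET_HALF) * n
                )
                coords.append(h)
                names.append(stem + suffix)
                resids.append(atom.residue_index)
                virt.append(True)
                pseudo.append(False)
        elif code == "CH3":
            coords.append(x[i].copy())
            names.append(_h_stem(atom.name) + "*")
            resids.append(atom.residue_index)
            virt.append(True)
            pseudo.append(True)
        elif code == "N":
            has_h = any(topology.is_hydrogen(j) for j in nbrs)
            if has_h:
                continue
            if len(nbrs) < 2:
                continue  # chain-terminal N without partner; no amide H
            s = sum(unit_to(i, j) for j in nbrs)
            h = x[i] - NH_BOND * s / np.linalg.norm(s)
            coords.append(h)
            names.append(_h_stem(atom.name))
            resids.append(atom.residue_index)
            virt.append(True)
            pseudo.append(False)

    return AugmentedConformation(
        coordinates=np.array(coords),
        names=names,
        residue_indices=np.array(resids),
        is_virtual=np.array(virt),
        is_pseudo=np.array(pseudo),
    )


def resolve_atom_spec(aug: AugmentedConformation, residue: int, spec: str):
    """Indices matching an atom spec; ``*`` wildcards prefix-match hydrogen
    and pseudo-site names (e.g. ``HD*`` spans both methyls of a Leu)."""
    in_res = np.flatnonzero(aug.residue_indices == residue)
    exact = [int(k) for k in in_res if aug.names[k] == spec]
    if exact:
        return exact
    if spec.endswith("*"):
        prefix = spec[:-1]
        hits = [
            int(k)
            for k in in_res
            if aug.names[k].startswith(prefix) and aug.names[k].startswith("H")
        ]
        return hits
    return []


# ---------------------------------------------------------------------------
# NOE analysis


@dataclass(frozen=True)
class NOERestraint:
    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    upper_bound: float  # nm

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise ValueError("NOE upper bound must be positive")


def _augmented_frames(traj_or_frames, topology):
    if isinstance(traj_or_frames, Trajectory):
        return [build_virtual_hydrogens(f, traj_or_frames.topology) for f in traj_or_frames.frames]
    if isinstance(traj_or_frames, Conformation):
        return [build_virtual_hydrogens(traj_or_frames, topology)]
    return list(traj_or_frames)


def noe_average_distance(frames, idx_i, idx_j) -> float:
    """<sum_pairs r^-3>_t^(-1/3) over augmented frames (nm).

    For multi-proton sites (wildcards), the per-frame inverse-cube
    contributions of all proton pairs are summed, the standard multiplet
    treatment; the result is never larger than any single-pair average.
    """
    inv3 = []
    for aug in frames:
        acc = 0.0
        for a in idx_i:
            for b in idx_j:
                d = np.linalg.norm(aug.coordinates[a] - aug.coordinates[b])
                if d <= 0:
                    raise ValueError("zero inter-proton distance in a frame")
                acc += d**-3
        inv3.append(acc)
    return float(np.mean(inv3)) ** (-1.0 / 3.0)


@dataclass
class DeviationReport:
    """Per-record deviations plus the binned summary of one observable."""

    kind: str
    edges: tuple
    counts: np.ndarray
    threshold: float
    n_significant: int
    records: list = field(default_factory=list)
    rejects: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)


def _bin_deviations(devs, edges) -> np.ndarray:
    """Half-open bins [e0,e1), ..., [e_last, inf); values below e0 uncounted."""
    counts = np.zeros(len(edges), dtype=int)
    for d in devs:
        if d < edges[0]:
            continue
        k = int(np.searchsorted(edges, d, side="right")) - 1
        counts[k] += 1
    return counts


def _side_correction(aug: AugmentedConformation, matches, corrections) -> float:
    n_pseudo = sum(1 for k in matches if aug.is_pseudo[k])
    if n_pseudo >= 2:
        return corrections["ch3ch3"]
    if n_pseudo == 1:
        return corrections["ch3"]
    if len(matches) >= 2:
        return corrections["ch2"]
    return 0.0


def noe_violation_report(
    traj_or_frames,
    restraints,
    topology: Topology | None = None,
    corrections: dict | None = None,
) -> DeviationReport:
    """Score r^-3-averaged distances against upper bounds.

    violation = max(0, d_calc - (upper_bound + pseudo-atom correction));
    unresolvable restraints are listed under ``rejects``, never dropped
    silently.
    """
    frames = _augmented_frames(traj_or_frames, topology)
    if corrections is None:
        corrections = load_corrections()
    records, rejects, viols = [], [], []
    aug0 = frames[0]
    for r in restraints:
        mi = resolve_atom_spec(aug0, r.residue_i, r.atom_i)
        mj = resolve_atom_spec(aug0, r.residue_j, r.atom_j)
        if not mi or not mj:
            rejects.append(r)
            continue
        corr = _side_correction(aug0, mi, corrections) + _side_correction(
            aug0, mj, corrections
        )
        d = noe_average_distance(frames, mi, mj)
        v = max(0.0, d - (r.upper_bound + corr))
        viols.append(v)
        records.append(
            {
                "restraint": r,
                "distance": d,
                "bound": r.upper_bound,
                "correction": corr,
                "violation": v,
                "wildcard": len(mi) > 1 or len(mj) > 1,
            }
        )
    counts = _bin_deviations(viols, NOE_BIN_EDGES)
    thr = SIGNIFICANCE["noe"]
    return DeviationReport(
        kind="noe",
        edges=NOE_BIN_EDGES,
        counts=counts,
        threshold=thr,
        n_significant=int(sum(1 for v in viols if v > thr)),
        records=records,
        rejects=rejects,
    )


# ---------------------------------------------------------------------------
# Karplus 3J couplings


@dataclass(frozen=True)
class KarplusParameters:
    """J(theta) = a cos^2(theta) + b cos(theta) + c, all in Hz."""

    a: float
    b: float
    c: float
    label: str = ""

    def __post_init__(self):
        if abs(self.b) >= self.a:
            raise ValueError("Karplus parameters require |b| < a")


PARDI_BACKBONE = KarplusParameters(6.4, -1.4, 1.9, "Pardi HN-HA")
DEMARCO_SIDECHAIN = KarplusParameters(9.5, -1.6, 1.8, "DeMarco HA-HB")


def karplus_j(theta_deg, params: KarplusParameters):
    """3J coupling (Hz) for dihedral angle(s) in degrees."""
    c = np.cos(np.deg2rad(theta_deg))
    return params.a * c**2 + params.b * c + params.c


def karplus_extrema(params: KarplusParameters):
    """(J_min, J_max) of the quadratic in cos(theta) over theta.

    With |b| < a the stationary point cos(theta) = -b/(2a) lies inside
    [-1, 1] and is the minimum; the maximum sits at cos(theta) = -sign(b)."""
    cands = [-1.0, 1.0, -params.b / (2.0 * params.a)]
    vals = [params.a * u * u + params.b * u + params.c for u in cands]
    return min(vals), max(vals)


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(m1 @ n2, n1 @ n2))


def j_couplings_from_structure(
    traj_or_frames,
    records,
    topology: Topology | None = None,
) -> tuple[np.ndarray, list]:
    """Frame-averaged 3J values for a table of coupling records.

    Each record needs ``residue``, ``atoms`` ("H-N-CA-HA" style, resolved
    within the residue on the virtual-H-augmented frame) and ``coupling``
    ("bb" -> Pardi backbone parameters, "sc" -> DeMarco side-chain).
    Returns per-record means (NaN for unresolved) and the unresolved list.
    """
    frames = _augmented_frames(traj_or_frames, topology)
    values = np.full(len(records), np.nan)
    unresolved = []
    for n, rec in enumerate(records):
        names = rec["atoms"].split("-")
        if len(names) != 4:
            unresolved.append(rec)
            continue
        params = PARDI_BACKBONE if rec.get("coupling", "bb") == "bb" else DEMARCO_SIDECHAIN
        try:
            idx = [frames[0].find(rec["residue"], nm) for nm in names]
        except KeyError:
            unresolved.append(rec)
            continue
        js = []
        for aug in frames:
            p = aug.coordinates
            theta = _dihedral(p[idx[0]], p[idx[1]], p[idx[2]], p[idx[3]])
            js.append(karplus_j(theta, params))
        values[n] = float(np.mean(js))
    return values, unresolved


def resolve_ambiguous_assignment(calc_pair, exp_pair):
    """Assign an unassigned experimental pair to the calculated pair.

    Chooses the pairing minimising the summed absolute deviation; on a tie
    the input order is kept.  Returns (exp_in_calc_order, deviations).
    """
    c1, c2 = calc_pair
    e1, e2 = exp_pair
    direct = abs(c1 - e1) + abs(c2 - e2)
    swapped = abs(c1 - e2) + abs(c2 - e1)
    if swapped < direct:
        return (e2, e1), (abs(c1 - e2), abs(c2 - e1))
    return (e1, e2), (abs(c1 - e1), abs(c2 - e2))


# ---------------------------------------------------------------------------
# S^2 order parameters


def s2_from_vectors(vectors: np.ndarray, r_eff: float | None = None) -> float:
    """Generalised order parameter of a bond vector over one time window:

    S^2 = 1/2 { 3 sum_ab <mu_a mu_b / r^3>^2 - <1/r^3>^2 } (r_eff)^6

    With a constrained (constant) bond length this reduces to the familiar
    1/2 (3 sum <mu_a mu_b>^2 - 1).  ``r_eff`` defaults to the mean length.
    """
    v = np.asarray(vectors, dtype=float)
    r = np.linalg.norm(v, axis=1)
    if np.any(r <= 0):
        raise ValueError("zero-length bond vector")
    mu = v / r[:, None]
    inv3 = r**-3
    if r_eff is None:
        r_eff = float(np.mean(r))
    q = np.einsum("ta,tb,t->ab", mu, mu, inv3) / len(r)
    mean_inv3 = float(np.mean(inv3))
    return 0.5 * (3.0 * float(np.sum(q * q)) - mean_inv3**2) * r_eff**6


def order_parameter(
    traj: Trajectory,
    pair: tuple[int, int],
    window_ps: float = 1000.0,
    superpose_selection=None,
    r_eff: float | None = None,
) -> float:
    """S^2 for atom pair (a, b): the ensemble-averaging expression evaluated
    per non-overlapping window, then averaged over windows (final partial
    window discarded).

    Frames should be superimposed beforehand to remove overall rotation;
    alternatively pass ``superpose_selection`` (index list) to fit every
    frame onto the first using those atoms.
    """
    from .analysis import superimpose  # local import avoids cycle at import time

    coords = traj.coordinates
    if superpose_selection is not None:
        ref = coords[0]
        fitted = [ref]
        for f in coords[1:]:
            _, moved = superimpose(ref, f, superpose_selection)
            fitted.append(moved)
        coords = np.array(fitted)
    a, b = pair
    vecs = coords[:, a, :] - coords[:, b, :]
    n_frames = len(vecs)
    if n_frames < 2:
        raise ValueError("need at least two frames")
    dt = traj.times[1] - traj.times[0]
    win = int(round(window_ps / dt))
    if win > n_frames:
        raise ValueError("window longer than trajectory")
    win = max(win, 2)
    n_windows = n_frames // win
    vals = [
        s2_from_vectors(vecs[k * win : (k + 1) * win], r_eff=r_eff)
        for k in range(n_windows)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# deviation histograms


def deviation_histograms(calc, exp, kind: str) -> DeviationReport:
    """Bin |calc - exp| with the edges appropriate to the observable kind
    ("J" or "S2"); records below the lowest edge are not binned."""
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape:
        raise ValueError("calculated and experimental sets differ in length")
    edges = {"J": J_BIN_EDGES, "S2": S2_BIN_EDGES, "noe": NOE_BIN_EDGES}[kind]
    devs = np.abs(calc - exp)
    thr = SIGNIFICANCE[kind]
    return DeviationReport(
        kind=kind,
        edges=edges,
        counts=_bin_deviations(devs, edges),
        threshold=thr,
        n_significant=int(np.sum(devs > thr)),
        records=[
            {"calc": float(a), "exp": float(b), "deviation": float(d)}
            for a, b, d in zip(calc, exp, devs)
        ],
    )
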