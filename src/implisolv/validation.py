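"""Single-structure validation against experimental NMR tables.

Runs the complete deviation-scoring chain — NOE bound violations, 3J
couplings and radius of gyration — on a crystal structure (e.g. PDB entry
2VB1 for hen egg white lysozyme) against user-supplied experimental
tables.  The experimental data files are not distributed with the package;
point ``tables_dir`` at a directory containing ``noe.tsv`` and optional
``jcoupling_*.tsv`` files in the documented tab-separated schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .analysis import radius_of_gyration
from .io import PDBRecordOptions, read_pdb, read_table
from .observables import (
    deviation_histograms,
    j_couplings_from_structure,
    noe_violation_report,
    resolve_ambiguous_assignment,
    karplus_extrema,
    PARDI_BACKBONE,
)

__all__ = ["score_coupling_table", "xray_validation"]


def score_coupling_table(traj_or_conf, table, topology=None):
    """Back-calculate a 3J table and score deviations.

    Handles ``pair:<id>`` stereo-specifically unassigned records by
    choosing the deviation-minimising pairing and ``cap_flag`` records by
    capping the experimental value at the Karplus curve maximum.
    Returns the DeviationReport.
    """
    records = table.to_dict("records")
    calc, unresolved = j_couplings_from_structure(traj_or_conf, records, topology)
    exp = np.array([float(r["value_hz"]) for r in records])
    jmax = karplus_extrema(PARDI_BACKBONE)[1]
    for k, r in enumerate(records):
        if int(r.get("cap_flag", 0)):
            exp[k] = min(exp[k], jmax)
    groups: dict = {}
    for k, r in enumerate(records):
        st = str(r.get("assignment_status", "assigned"))
        if st.startswith("pair:"):
            groups.setdefault(st, []).append(k)
    for members in groups.values():
        if len(members) != 2:
            raise ValueError("unassigned pair without exactly two partners")
        i, j = members
        (exp[i], exp[j]), _ = resolve_ambiguous_assignment(
            (calc[i], calc[j]), (exp[i], exp[j])
        )
    keep = [k for k in range(len(records)) if not np.isnan(calc[k])]
    report = deviation_histograms(calc[keep], exp[keep], "J")
    report.rejects = unresolved
    return report


def xray_validation(pdb_path, tables_dir, type_overrides=None) -> dict:
    """NOE / 3J / Rgyr validation of a crystal structure.

    ``tables_dir`` must contain ``noe.tsv``; ``jcoupling_bb1.tsv`` and
    friends are scored when present.  AltLoc ambiguities resolve to the
    highest-occupancy conformation.
    """
    tables_dir = Path(tables_dir)
    topo, traj = read_pdb(
        pdb_path,
        PDBRecordOptions(altloc_policy="highest-occupancy", model_selection="first"),
        type_overrides=type_overrides,
    )
    conf = traj.frames[0]
    out = {
        "rgyr_nm": radius_of_gyration(conf, topo),
        "n_atoms": topo.n_atoms,
    }
    noe_path = tables_dir / "noe.tsv"
    if noe_path.exists():
        restraints = read_table(noe_path, "noe")
        rep = noe_violation_report(conf, restraints, topo)
        out["noe_n_bounds"] = len(restraints)
        out["noe_histogram"] = rep.counts.tolist()
        out["noe_violations_gt_0.1nm"] = int(rep.counts[1:].sum())
        out["noe_violations_0.05_0.1nm"] = int(rep.counts[0])
        out["noe_rejects"] = len(rep.rejects)
    for stem in ("bb1", "bb2", "sc1", "sc2"):
        path = tables_dir / f"jcoupling_{stem}.tsv"
        if path.exists():
            table = read_table(path, "jcoupling")
            rep = score_coupling_table(conf, table, topo)
            out[f"j_{stem}_n"] = rep.n_records
            out[f"j_{stem}_deviations_gt_2hz"] = rep.n_significant
            out[f"j_{stem}_histogram"] = rep.counts.tolist()
    return out
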