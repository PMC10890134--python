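"""Per-atom nonbonded parameter assignment from a plain CSV table.

The table stands in for force-field typing: each row gives mass (amu),
partial charge (e), LJ well depth epsilon (kcal/mol) and Rmin/2 (Å) for
atoms matched by (segid, resname, name), any of which may be the wildcard
``*``. The most specific matching row wins (ties broken toward the last
row in file order), so a generic ``*,*,CA`` row can be overridden by a
``PROT,ALA,CA`` row for one residue type.

Expected header: ``segid,resname,name,mass,charge,epsilon,rmin_half``.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import pandas as pd

from .errors import FormatError, ParameterAssignmentError
from .model import Topology

log = logging.getLogger(__name__)

__all__ = ["assign_parameters", "read_parameter_table"]

_COLUMNS = ["segid", "resname", "name", "mass", "charge", "epsilon", "rmin_half"]


def read_parameter_table(path) -> pd.DataFrame:
    """Read and validate a parameter CSV."""
    table = pd.read_csv(path, dtype={"segid": str, "resname": str, "name": str})
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: parameter table missing column(s) {', '.join(missing)}")
    return table


def assign_parameters(topology: Topology, table) -> Topology:
    """Return a new Topology with masses/charges/LJ parameters filled in.

    ``table`` is a path to a CSV or an already-loaded DataFrame. Every atom
    must match at least one row; unmatched atoms are collected and reported
    together.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_parameter_table(table)

    rows = []
    for order, row in enumerate(table.itertuples(index=False)):
        specificity = sum(
            str(v).strip() != "*" for v in (row.segid, row.resname, row.name)
        )
        rows.append((specificity, order, row))

    def matches(row, atom) -> bool:
        for pattern, value in (
            (row.segid, atom.segment_id),
            (row.resname, atom.residue_name),
            (row.name, atom.atom_name),
        ):
            pattern = str(pattern).strip()
            if pattern != "*" and pattern != value:
                return False
        return True

    new_atoms, unmatched = [], []
    for atom in topology:
        best = None
        for specificity, order, row in rows:
            if matches(row, atom):
                key = (specificity, order)
                if best is None or key > best[0]:
                    best = (key, row)
        if best is None:
            unmatched.append(atom.key)
            continue
        row = best[1]
        new_atoms.append(replace(
            atom,
            mass=float(row.mass),
            charge=float(row.charge),
            lj_epsilon=float(row.epsilon),
            lj_rmin_half=float(row.rmin_half),
        ))
    if unmatched:
        listing = ", ".join(repr(k) for k in unmatched)
        raise ParameterAssignmentError(
            f"{len(unmatched)} atom(s) matched no parameter row: {listing}",
            unmatched)
    log.info("assign_parameters: %d atoms from %d rows", len(new_atoms),
             len(rows))
    return topology.with_atoms(new_atoms)
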