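"""Liquid-drop-model and ionic descriptors.

Two theoretical descriptors characterise each oxide:

* the Wigner-Seitz radius ``r_wz = (3 M / (4 pi rho))^(1/3)`` of the liquid
  drop model — the radius of the imaginary basic element (molecule or
  crystal unit) inside a nanoparticle treated as a densely packed spherical
  drop, with ``M`` the molecular weight (g/mol) and ``rho`` the bulk mass
  density (g/cm^3);
* the covalent index ``CI = chi^2 * r`` — the cation's Pauling
  electronegativity squared times its Pauling ionic radius (pm), a proxy for
  a released metal ion's affinity to biomolecule binding sites.

The study table prints ``r_wz`` in an undefined "a.u." scale.  Reverse
evaluation of the printed column shows it equals the raw Eq.-form value
(M in g/mol, rho in g/cm^3) divided by 10, verified to three decimals for
23 of the 24 oxides; that factor is :data:`RWZ_TABLE_SCALE`.  The single
deviating row (CoO, printed 0.144 vs computed 0.141) is kept as printed in
the fixture and reported by :func:`compute_descriptor_table`.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from nanoqsar.dataset_io import Dataset, IonEntry, molecular_weight

__all__ = [
    "RWZ_TABLE_SCALE",
    "wigner_seitz_radius",
    "covalent_index",
    "compute_descriptor_table",
]

#: Empirical scale mapping the raw Wigner-Seitz radius (M in g/mol, rho in
#: g/cm^3) onto the study table's printed "a.u." column.  The factor was
#: reverse-engineered from the printed values; its physical meaning is not
#: stated in the source and is not interpreted here.
RWZ_TABLE_SCALE = 0.1

#: Default tolerances for the fixture discrepancy report.
DEFAULT_RWZ_TOLERANCE = 0.003
DEFAULT_CI_TOLERANCE = 0.01


def wigner_seitz_radius(mol_weight: float, density: float) -> float:
    """Wigner-Seitz radius in table units for a molecular weight and density.

    Evaluates ``(3 M / (4 pi rho))^(1/3)`` and applies
    :data:`RWZ_TABLE_SCALE`.

    Raises
    ------
    ValueError
        If either input is not strictly positive.
    """
    if not mol_weight > 0:
        raise ValueError("molecular weight must be > 0")
    if not density > 0:
        raise ValueError("density must be > 0")
    return (3.0 * mol_weight / (4.0 * math.pi * density)) ** (1.0 / 3.0) * RWZ_TABLE_SCALE


def covalent_index(electronegativity: float, ionic_radius: float) -> float:
    """Covalent index ``chi^2 * r`` with the ionic radius in pm.

    Raises
    ------
    ValueError
        If either input is not strictly positive.
    """
    if not electronegativity > 0:
        raise ValueError("electronegativity must be > 0")
    if not ionic_radius > 0:
        raise ValueError("ionic radius must be > 0")
    return electronegativity**2 * ionic_radius


def compute_descriptor_table(
    dataset: Dataset,
    masses: Mapping[str, float],
    ion_table: Mapping[str, IonEntry],
    rwz_tolerance: float = DEFAULT_RWZ_TOLERANCE,
    ci_tolerance: float = DEFAULT_CI_TOLERANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute both descriptors for every record and flag table deviations.

    Returns
    -------
    table : DataFrame
        One row per record with computed and (if present) tabulated
        descriptor values and their absolute deviations.
    report : DataFrame
        The subset of rows whose tabulated value deviates from the computed
        one beyond ``rwz_tolerance`` / ``ci_tolerance``.

    Raises
    ------
    KeyError
        If a record's oxide is missing from ``ion_table`` or an element from
        ``masses``; the error names the offending formula.
    """
    rows = []
    for record in dataset:
        try:
            mw = molecular_weight(record.formula, masses)
        except KeyError as exc:
            raise KeyError(f"{record.formula}: {exc.args[0]}") from exc
        if record.formula not in ion_table:
            raise KeyError(f"{record.formula}: missing from the ion-property table")
        ion = ion_table[record.formula]
        rwz = wigner_seitz_radius(mw, record.density)
        ci = covalent_index(ion.electronegativity, ion.ionic_radius)
        rows.append(
            {
                "formula": record.formula,
                "mol_weight": mw,
                "rwz_computed": rwz,
                "ci_computed": ci,
                "rwz_table": record.rwz,
                "ci_table": record.ci,
                "rwz_abs_dev": abs(rwz - record.rwz) if record.rwz is not None else None,
                "ci_abs_dev": abs(ci - record.ci) if record.ci is not None else None,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "formula",
            "mol_weight",
            "rwz_computed",
            "ci_computed",
            "rwz_table",
            "ci_table",
            "rwz_abs_dev",
            "ci_abs_dev",
        ],
    )
    if table.empty:
        return table, table.copy()
    flagged = (table["rwz_abs_dev"].fillna(0) > rwz_tolerance) | (
        table["ci_abs_dev"].fillna(0) > ci_tolerance
    )
    return table, table[flagged].reset_index(drop=True)
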