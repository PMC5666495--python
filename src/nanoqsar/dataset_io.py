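"""Nanoparticle dataset and reference-table I/O.

The study data are a table of 24 silica- and metal-oxide nanoparticles with
measured hydrodynamic size (nm), bulk mass density (g/cm^3), two theoretical
descriptors (Wigner-Seitz radius, covalent index), and the residual ZHE1
enzymatic activity (mmol/mg*min) under nanoparticle exposure.  Five records
form the external validation set; the remaining 19 are the training set.
The full table, an ion-property table (Pauling electronegativity and ionic
radius per oxide), and a standard-atomic-weight table are bundled with the
package and addressable by the name ``"builtin"``.

All tables are plain CSV (comma separator, ``.`` decimal, UTF-8, header
required).  A leading ``# control_activity: <x>`` comment line on a dataset
CSV records the activity of the nanoparticle-free control assay.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "FormulaError",
    "SchemaError",
    "NPRecord",
    "Dataset",
    "IonEntry",
    "parse_formula",
    "format_formula",
    "molecular_weight",
    "load_atomic_masses",
    "load_dataset",
    "write_dataset",
    "load_ion_table",
]

# The 118 IUPAC element symbols, used to reject mistyped formulas.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

DATASET_COLUMNS = ("formula", "hydro_size", "density", "activity", "subset")
SUBSETS = ("train", "test")


class FormulaError(ValueError):
    """A chemical formula string could not be parsed."""


class SchemaError(ValueError):
    """A CSV table does not match the expected schema."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula like ``"Co3O4"`` into ``{"Co": 3, "O": 4}``.

    Element symbols may each be followed by an optional integer count.
    Charge, hydration, and isotope notations are not supported.

    Raises
    ------
    FormulaError
        If the string is empty, contains non-formula characters, or names an
        unknown element symbol.
    """
    if not formula:
        raise FormulaError("empty formula string")
    composition: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable token {formula[pos:match.start()]!r} in formula {formula!r}"
            )
        pos = match.end()
        symbol, count = match.group(1), match.group(2)
        if symbol not in ELEMENT_SYMBOLS:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        if count == "0":
            raise FormulaError(f"zero count for element {symbol!r} in formula {formula!r}")
        composition[symbol] = composition.get(symbol, 0) + (int(count) if count else 1)
    if pos != len(formula):
        raise FormulaError(f"unparseable trailing token {formula[pos:]!r} in formula {formula!r}")
    if not composition:
        raise FormulaError(f"no element symbols found in formula {formula!r}")
    return composition


def format_formula(composition: Mapping[str, int]) -> str:
    """Render an element->count map back to a canonical formula string.

    Elements appear in mapping order; unit counts are omitted, so
    ``format_formula(parse_formula(s)) == s`` for canonical inputs.
    """
    parts = []
    for symbol, count in composition.items():
        if symbol not in ELEMENT_SYMBOLS:
            raise FormulaError(f"unknown element symbol {symbol!r}")
        if count < 1:
            raise FormulaError(f"non-positive count for element {symbol!r}")
        parts.append(symbol if count == 1 else f"{symbol}{count}")
    return "".join(parts)


def molecular_weight(
    composition: Mapping[str, int] | str, masses: Mapping[str, float]
) -> float:
    """Molecular weight in g/mol of a composition under an atomic-mass table.

    ``composition`` may be a formula string, which is parsed first.

    Raises
    ------
    KeyError
        If an element is missing from ``masses``.
    """
    if isinstance(composition, str):
        composition = parse_formula(composition)
    total = 0.0
    for symbol, count in composition.items():
        if symbol not in masses:
            raise KeyError(f"element {symbol!r} missing from the atomic-mass table")
        total += count * masses[symbol]
    return total


@dataclass(frozen=True)
class NPRecord:
    """One nanoparticle record of the study table.

    ``rwz`` and ``ci`` hold the descriptor values as printed in the source
    table when loaded from the bundled fixture; they may be ``None`` for raw
    datasets and filled in by the descriptors module.
    """

    formula: str
    hydro_size: float  # hydrodynamic size in Holtfreter's medium, nm
    density: float  # bulk mass density, g/cm^3
    activity: float  # residual ZHE1 activity, mmol/mg*min
    subset: str  # "train" or "test"
    rwz: float | None = None  # Wigner-Seitz radius, table units
    ci: float | None = None  # covalent index, dimensionless
    record_id: str | None = None

    def __post_init__(self) -> None:
        parse_formula(self.formula)
        if not self.hydro_size > 0:
            raise ValueError(f"{self.formula}: hydro_size must be > 0")
        if not self.density > 0:
            raise ValueError(f"{self.formula}: density must be > 0")
        if self.activity < 0:
            raise ValueError(f"{self.formula}: activity must be >= 0")
        if self.subset not in SUBSETS:
            raise ValueError(f"{self.formula}: subset must be one of {SUBSETS}")
        if self.record_id is None:
            object.__setattr__(self, "record_id", self.formula)


@dataclass
class Dataset:
    """Ordered collection of :class:`NPRecord` plus the assay control activity."""

    records: list[NPRecord] = field(default_factory=list)
    control_activity: float | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def formulas(self) -> list[str]:
        return [r.formula for r in self.records]

    def subset(self, label: str) -> "Dataset":
        """Records whose subset marker equals ``label`` ("train" or "test")."""
        return Dataset(
            [r for r in self.records if r.subset == label], self.control_activity
        )

    def get(self, formula: str) -> NPRecord:
        for r in self.records:
            if r.formula == formula:
                return r
        raise KeyError(formula)

    def to_frame(self) -> pd.DataFrame:
        """The records as a DataFrame indexed by record id."""
        frame = pd.DataFrame(
            {
                "formula": [r.formula for r in self.records],
                "hydro_size": [r.hydro_size for r in self.records],
                "density": [r.density for r in self.records],
                "rwz": [r.rwz for r in self.records],
                "ci": [r.ci for r in self.records],
                "activity": [r.activity for r in self.records],
                "subset": [r.subset for r in self.records],
            },
            index=pd.Index([r.record_id for r in self.records], name="record_id"),
        )
        return frame

    def with_descriptors(self, rwz: Mapping[str, float], ci: Mapping[str, float]) -> "Dataset":
        """A copy whose records carry the given descriptor values (keyed by record id)."""
        new = [
            replace(r, rwz=rwz.get(r.record_id, r.rwz), ci=ci.get(r.record_id, r.ci))
            for r in self.records
        ]
        return Dataset(new, self.control_activity)


def _builtin(name: str):
    return resources.files("nanoqsar.data").joinpath(name)


def load_atomic_masses(source: str | Path = "builtin") -> dict[str, float]:
    """Standard atomic weights (g/mol) keyed by element symbol.

    The bundled table carries the IUPAC 2021 standard atomic weights rounded
    to four decimals for every element occurring in the study oxides.
    """
    if source == "builtin":
        with resources.as_file(_builtin("atomic_masses.csv")) as path:
            return load_atomic_masses(path)
    frame = pd.read_csv(Path(source))
    if not {"symbol", "atomic_mass"}.issubset(frame.columns):
        raise SchemaError("atomic-mass table needs columns symbol, atomic_mass")
    masses = dict(zip(frame["symbol"], frame["atomic_mass"].astype(float)))
    for symbol, mass in masses.items():
        if symbol not in ELEMENT_SYMBOLS:
            raise SchemaError(f"unknown element symbol {symbol!r} in mass table")
        if not mass > 0:
            raise SchemaError(f"non-positive atomic mass for {symbol!r}")
    return masses


def _read_control_comment(path: Path) -> float | None:
    with open(path, "r", encoding="utf-8") as handle:
        first = handle.readline()
    if first.startswith("#") and "control_activity" in first:
        return float(first.split(":", 1)[1])
    return None


def load_dataset(source: str | Path = "builtin") -> Dataset:
    """Load a nanoparticle dataset from CSV, or the bundled study table.

    Required columns: ``formula, hydro_size, density, activity, subset``;
    ``rwz`` and ``ci`` are optional.  Every record is validated against the
    :class:`NPRecord` invariants and formulas must be unique.

    Raises
    ------
    SchemaError
        On a missing column or duplicate formula.
    ValueError
        On a non-numeric cell, reported with its row index.
    """
    if source == "builtin":
        with resources.as_file(_builtin("study_table.csv")) as path:
            return load_dataset(path)
    path = Path(source)
    control = _read_control_comment(path)
    frame = pd.read_csv(path, comment="#")
    missing = set(DATASET_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"dataset CSV is missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        numeric = {}
        for col in ("hydro_size", "density", "activity", "rwz", "ci"):
            if col not in frame.columns:
                numeric[col] = None
                continue
            raw = getattr(row, col)
            if pd.isna(raw):
                numeric[col] = None
                continue
            try:
                numeric[col] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {i}: non-numeric value {raw!r} in column {col!r}") from exc
        for col in ("hydro_size", "density", "activity"):
            if numeric[col] is None:
                raise ValueError(f"row {i}: missing value in required column {col!r}")
        records.append(
            NPRecord(
                formula=str(row.formula),
                hydro_size=numeric["hydro_size"],
                density=numeric["density"],
                activity=numeric["activity"],
                subset=str(row.subset),
                rwz=numeric["rwz"],
                ci=numeric["ci"],
            )
        )
    formulas = [r.formula for r in records]
    if len(set(formulas)) != len(formulas):
        dupes = sorted({f for f in formulas if formulas.count(f) > 1})
        raise SchemaError(f"duplicate formulas in dataset: {dupes}")
    return Dataset(records, control)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset to CSV in the format :func:`load_dataset` reads."""
    path = Path(path)
    frame = dataset.to_frame().reset_index(drop=True)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if dataset.control_activity is not None:
            handle.write(f"# control_activity: {dataset.control_activity}\n")
        frame.to_csv(handle, index=False)


@dataclass(frozen=True)
class IonEntry:
    """Cation properties used by the covalent index, keyed by oxide formula.

    Mixed-valence oxides (Fe3O4, Co3O4) need a single effective pair, which
    is why the key is the oxide and not the bare cation.  The bundled radii
    are back-computed from the study's printed covalent-index column
    (r = CI / chi^2), since the original chi/r sources are not printed.
    """

    oxide_formula: str
    element: str
    electronegativity: float  # Pauling chi, dimensionless
    ionic_radius: float  # Pauling ionic radius, pm

    def __post_init__(self) -> None:
        if not 0.5 < self.electronegativity < 4.5:
            raise ValueError(f"{self.oxide_formula}: electronegativity outside (0.5, 4.5)")
        if not 30 < self.ionic_radius < 200:
            raise ValueError(f"{self.oxide_formula}: ionic radius outside (30, 200) pm")


def load_ion_table(source: str | Path = "builtin") -> dict[str, IonEntry]:
    """Per-oxide cation electronegativity and ionic radius (pm).

    Raises
    ------
    SchemaError
        On a missing column or a duplicate oxide key.
    """
    if source == "builtin":
        with resources.as_file(_builtin("ion_properties.csv")) as path:
            return load_ion_table(path)
    frame = pd.read_csv(Path(source))
    required = {"oxide_formula", "element", "electronegativity", "ionic_radius"}
    if not required.issubset(frame.columns):
        raise SchemaError(f"ion table needs columns {sorted(required)}")
    table: dict[str, IonEntry] = {}
    for row in frame.itertuples(index=False):
        key = str(row.oxide_formula)
        if key in table:
            raise SchemaError(f"duplicate oxide key {key!r} in ion table")
        table[key] = IonEntry(
            oxide_formula=key,
            element=str(row.element),
            electronegativity=float(row.electronegativity),
            ionic_radius=float(row.ionic_radius),
        )
    return table
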