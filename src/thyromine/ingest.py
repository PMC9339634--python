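"""Reading and cleaning raw clinical tables.

Supports the three dialects the pipeline consumes: UCI ``.data``
comma-separated files (no header, ``?`` as missing marker), RFC-4180 CSV
with a header row, and xlsx spreadsheets (first sheet, first row as
header). All dialects are normalized into a :class:`RawTable` whose cells
are strings, with one canonical missing marker regardless of source
dialect. Cleaning is limited to attribute selection and removal of
incomplete records; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

#: Canonical missing-value marker. Reserved: no legal category label may
#: equal it.
MISSING = "?"


class IngestError(Exception):
    """Raised for unreadable files, ragged rows, or bad attribute requests."""


@dataclass
class RawTable:
    """An ordered table of records with string cells.

    ``records`` maps attribute name -> raw value (always ``str``; numeric
    strings are preserved verbatim, no coercion). Missing cells hold
    :data:`MISSING`.
    """

    records: list[dict[str, str]]
    attribute_names: list[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        names = set(self.attribute_names)
        if len(names) != len(self.attribute_names):
            raise IngestError("duplicate attribute names in table")
        for i, rec in enumerate(self.records):
            if set(rec) != names:
                raise IngestError(
                    f"record {i} attributes {sorted(rec)} do not match "
                    f"table attributes {self.attribute_names}"
                )

    @property
    def n_records(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[rec[a] for a in self.attribute_names] for rec in self.records],
            columns=self.attribute_names,
            dtype=object,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source_label: str = "") -> "RawTable":
        names = [str(c) for c in df.columns]
        records = [
            {a: _normalize_cell(v) for a, v in zip(names, row)}
            for row in df.itertuples(index=False, name=None)
        ]
        return cls(records=records, attribute_names=names, source_label=source_label)


def _normalize_cell(value: object) -> str:
    """Render a raw cell as a string, mapping blank/NaN/``?`` to MISSING."""
    if value is None:
        return MISSING
    if isinstance(value, float) and pd.isna(value):
        return MISSING
    s = str(value).strip()
    if s in ("", "?", "NA", "nan", "None"):
        return MISSING
    return s


def read_table(
    path: str | Path,
    dialect: str,
    column_names: Sequence[str] | None = None,
) -> RawTable:
    """Read a raw clinical table in one of the supported dialects.

    Parameters
    ----------
    path
        File to read.
    dialect
        One of ``uci_data`` (comma-separated, no header, ``?`` missing),
        ``csv`` (header row), ``spreadsheet`` (xlsx, first sheet).
    column_names
        Required for ``uci_data`` (the dialect carries no header); ignored
        otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"input file not found: {path}")
    if dialect == "uci_data":
        if column_names is None:
            raise IngestError("uci_data dialect requires column_names")
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                fields = line.split(",")
                if len(fields) != len(column_names):
                    raise IngestError(
                        f"ragged row {i}: {len(fields)} fields, "
                        f"expected {len(column_names)}"
                    )
                rows.append(fields)
        df = pd.DataFrame(rows, columns=list(column_names), dtype=object)
    elif dialect == "csv":
        try:
            df = pd.read_csv(path, dtype=object, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise IngestError(f"cannot parse CSV {path}: {exc}") from exc
    elif dialect == "spreadsheet":
        try:
            df = pd.read_excel(path, sheet_name=0, dtype=object)
        except Exception as exc:
            raise IngestError(f"cannot parse spreadsheet {path}: {exc}") from exc
    else:
        raise IngestError(f"unknown dialect: {dialect!r}")
    return RawTable.from_dataframe(df, source_label=str(path))


@dataclass
class AttributeSelection:
    """Ordered subset of attributes to retain, with optional renaming.

    ``rename_map`` maps source name -> canonical name and is applied before
    selection, so ``names`` refers to canonical names. The map may carry
    alias spellings (several source names for one canonical name) to absorb
    dialect variation; renaming a single table must still be injective,
    which :func:`select_attributes` enforces.
    """

    names: list[str]
    rename_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.names:
            raise IngestError("attribute selection is empty")
        if len(set(self.names)) != len(self.names):
            raise IngestError("attribute selection has duplicate names")


def select_attributes(raw: RawTable, sel: AttributeSelection) -> RawTable:
    """Retain exactly ``sel.names`` (in order), after applying renames."""
    renamed = [sel.rename_map.get(a, a) for a in raw.attribute_names]
    if len(set(renamed)) != len(renamed):
        raise IngestError("rename_map collapses two attributes into one name")
    missing = [n for n in sel.names if n not in renamed]
    if missing:
        raise IngestError(f"unknown attribute name(s): {missing}")
    index = {name: i for i, name in enumerate(renamed)}
    old_names = raw.attribute_names
    records = [
        {n: rec[old_names[index[n]]] for n in sel.names} for rec in raw.records
    ]
    return RawTable(records=records, attribute_names=list(sel.names),
                    source_label=raw.source_label)


def drop_incomplete(raw: RawTable) -> RawTable:
    """Remove every record holding the missing marker in any attribute.

    Order is preserved; an empty result is legal. Idempotent.
    """
    kept = [
        rec for rec in raw.records
        if all(v != MISSING for v in rec.values())
    ]
    return RawTable(records=kept, attribute_names=list(raw.attribute_names),
                    source_label=raw.source_label)


# ---------------------------------------------------------------------------
# Bundled dataset presets
# ---------------------------------------------------------------------------

#: Column order of the UCI thyroid "sick" database (29 attributes + class;
#: the final field concatenates the class label and a record id as
#: ``negative.|3733``).
SICK_COLUMNS: tuple[str, ...] = (
    "age", "sex", "on_thyroxine", "query_on_thyroxine",
    "on_antithyroid_medication", "sick", "pregnant", "thyroid_surgery",
    "I131_treatment", "query_hypothyroid", "query_hyperthyroid", "lithium",
    "goitre", "tumor", "hypopituitary", "psych", "TSH_measured", "TSH",
    "T3_measured", "T3", "TT4_measured", "TT4", "T4U_measured", "T4U",
    "FTI_measured", "FTI", "TBG_measured", "TBG", "referral_source", "class",
)

#: The 21 attributes retained for Dataset-I, with canonical names matching
#: the mined-rule vocabulary.
DATASET1_SELECTION = AttributeSelection(
    names=[
        "Age", "Sex", "On_thyroxine", "On_antithyroid_med", "Sick",
        "Pregnant", "Thyroid_surgery", "I131", "Query_hypothyroid",
        "Query_hyperthyroid", "Lithium", "Goiter", "Tumor", "Hypopituitary",
        "Psych", "TSH", "T3", "TT4", "T4U", "FTI", "Class",
    ],
    rename_map={
        "age": "Age", "sex": "Sex", "on_thyroxine": "On_thyroxine",
        "on_antithyroid_medication": "On_antithyroid_med", "sick": "Sick",
        "pregnant": "Pregnant", "thyroid_surgery": "Thyroid_surgery",
        "I131_treatment": "I131", "query_hypothyroid": "Query_hypothyroid",
        "query_hyperthyroid": "Query_hyperthyroid", "lithium": "Lithium",
        "goitre": "Goiter", "tumor": "Tumor", "hypopituitary": "Hypopituitary",
        "psych": "Psych", "class": "Class",
    },
)

#: The 15 attributes retained for Dataset-II (Z-Alizadeh Sani), canonical
#: names matching the mined-rule vocabulary.
DATASET2_SELECTION = AttributeSelection(
    names=[
        "Age", "Gender", "Diabetes_mellitus", "Hypertension",
        "Current_smoker", "Ex_smoker", "Obesity", "CRF", "CVA", "AD",
        "Edema", "LR", "Dyspnea", "CAD", "Class",
    ],
    rename_map={
        "DM": "Diabetes_mellitus", "HTN": "Hypertension",
        "Current Smoker": "Current_smoker", "EX-Smoker": "Ex_smoker",
        "Ex-Smoker": "Ex_smoker", "Airway disease": "AD",
        "Airway Disease": "AD", "Lung rales": "LR", "Lung Rales": "LR",
        "Cath": "CAD", "Cardiovascular Disease": "CAD",
        "Thyroid Disease": "Class",
    },
)


def read_sick_data(path: str | Path) -> RawTable:
    """Read the UCI sick ``.data`` file, splitting the trailing
    ``class|record-id`` field into a clean class label."""
    raw = read_table(path, "uci_data", column_names=SICK_COLUMNS)
    for rec in raw.records:
        cls = rec["class"].split("|")[0].strip().rstrip(".")
        rec["class"] = cls if cls else MISSING
    return raw


def clean_dataset1(raw: RawTable, age_filter: bool = False) -> RawTable:
    """Select the 21 Dataset-I attributes and drop incomplete records.

    ``age_filter=True`` additionally restricts to ages in [20, 80], the
    range spanned by the bundled age bins; with ``age_filter=False`` ages
    outside the bins will surface later as discretization errors unless the
    discretizer is told to drop them.
    """
    sel = select_attributes(raw, DATASET1_SELECTION)
    clean = drop_incomplete(sel)
    if age_filter:
        kept = []
        for rec in clean.records:
            try:
                age = float(rec["Age"])
            except ValueError:
                continue
            if 20 <= age <= 80:
                kept.append(rec)
        clean = RawTable(kept, list(clean.attribute_names), clean.source_label)
    return clean
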