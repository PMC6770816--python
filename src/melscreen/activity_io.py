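"""Reading, validating and writing ChEMBL-dialect bioactivity tables.

All tabular data enters and leaves the pipeline through this module.
Tables are plain CSV/TSV using the public ChEMBL export header
vocabulary (``molecule_chembl_id``, ``assay_chembl_id``, ...) or the
package's internal short names.  Delimiter is auto-detected between
comma and tab; encoding is UTF-8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

STANDARD_TYPES = ("IC50", "EC50", "Ki", "Kd", "AC50", "Potency",
                  "Inhibition", "Activity")
RELATIONS = ("=", ">", "<", ">=", "<=", "~")

#: column map from the ChEMBL public export header to internal names
CHEMBL_ACTIVITY_COLUMNS: Mapping[str, str] = {
    "activity_id": "record_id",
    "molecule_chembl_id": "compound_id",
    "assay_chembl_id": "assay_id",
    "target_chembl_id": "target_id",
    "standard_type": "standard_type",
    "standard_relation": "standard_relation",
    "standard_value": "standard_value",
    "standard_units": "standard_units",
    "activity_comment": "activity_comment",
}

CHEMBL_COMPOUND_COLUMNS: Mapping[str, str] = {
    "molecule_chembl_id": "compound_id",
    "canonical_smiles": "smiles",
    "pref_name": "pref_name",
    "max_phase": "max_phase",
}

CHEMBL_ASSAY_COLUMNS: Mapping[str, str] = {
    "assay_chembl_id": "assay_id",
    "assay_description": "description",
    "assay_type": "assay_type",
    "target_class": "target_class",
    "assay_organism": "organism",
    "assay_cell_type": "cell_line",
    "assay_tissue": "tissue",
    "bao_format": "bao_format",
}

_ACTIVITY_MANDATORY = ("record_id", "compound_id", "assay_id",
                       "standard_type", "standard_value", "standard_units")
_COMPOUND_MANDATORY = ("compound_id", "smiles")
_ASSAY_MANDATORY = ("assay_id", "description")


class TableFormatError(ValueError):
    """A table is missing a mandatory column for its dialect."""


@dataclass
class ActivityRecord:
    """One experimental measurement of one compound in one assay."""

    record_id: str
    compound_id: str
    assay_id: str
    target_id: Optional[str] = None
    standard_type: str = "IC50"
    standard_relation: str = "="
    standard_value: Optional[float] = None
    standard_units: Optional[str] = None
    activity_comment: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.standard_relation:
            self.standard_relation = "="
        if self.standard_value is not None and self.standard_value < 0:
            raise ValueError(
                f"negative standard_value in record {self.record_id!r}")


@dataclass
class CompoundProfile:
    """Structure, naming and clinical-phase metadata for one compound."""

    compound_id: str
    smiles: Optional[str] = None
    pref_name: Optional[str] = None
    max_phase: int = 0
    descriptors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_phase not in (0, 1, 2, 3, 4):
            raise ValueError(
                f"max_phase must be 0-4, got {self.max_phase!r}")


@dataclass
class AssayProfile:
    """Metadata for one assay, including the cardiovascular flag."""

    assay_id: str
    description: str = ""
    assay_type: str = "other"
    target_class: str = ""
    organism: str = ""
    cell_line: Optional[str] = None
    tissue: Optional[str] = None
    bao_format: Optional[str] = None
    is_cardiovascular: bool = False
    cv_matched_term: Optional[str] = None
    n_molecules_seen: int = 0


@dataclass
class LinkedTable:
    """Activity records joined to their compound and assay profiles."""

    records: list[ActivityRecord]
    compounds: dict[str, CompoundProfile]
    assays: dict[str, AssayProfile]
    orphans: list[ActivityRecord]

    def iter_resolved(self) -> Iterable[tuple[ActivityRecord,
                                              CompoundProfile, AssayProfile]]:
        for rec in self.records:
            yield rec, self.compounds[rec.compound_id], self.assays[rec.assay_id]


def _read_frame(path: str | Path) -> pd.DataFrame:
    # sniff comma vs tab from the header line
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       encoding="utf-8")


def _rename(df: pd.DataFrame, dialect: str,
            mapping: Mapping[str, str]) -> pd.DataFrame:
    if dialect == "chembl_export":
        return df.rename(columns=dict(mapping))
    if dialect == "internal":
        return df
    raise ValueError(f"unknown dialect {dialect!r}")


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{what} table is missing mandatory column(s): "
            + ", ".join(missing))


def read_activity_table(path: str | Path,
                        dialect: str = "internal") -> list[ActivityRecord]:
    """Read a bioactivity table into :class:`ActivityRecord` objects.

    Malformed numeric values are reported as warnings; the record is
    retained with ``standard_value=None``.  Row order is preserved.
    """
    df = _rename(_read_frame(path), dialect, CHEMBL_ACTIVITY_COLUMNS)
    _require(df, _ACTIVITY_MANDATORY, "activity")
    records: list[ActivityRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "standard_value", "")
        value: Optional[float] = None
        if str(raw).strip() != "":
            try:
                value = float(raw)
            except ValueError:
                warnings.warn(
                    f"row {i}: unparseable standard_value {raw!r}; "
                    "value dropped", stacklevel=2)
        rel = str(getattr(row, "standard_relation", "") or "").strip() or "="
        records.append(ActivityRecord(
            record_id=str(row.record_id),
            compound_id=str(row.compound_id),
            assay_id=str(row.assay_id),
            target_id=str(getattr(row, "target_id", "")) or None,
            standard_type=str(row.standard_type),
            standard_relation=rel,
            standard_value=value,
            standard_units=str(row.standard_units) or None,
            activity_comment=str(getattr(row, "activity_comment", ""))
            or None,
        ))
    _check_unique([r.record_id for r in records], "record_id")
    return records


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def activity_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """Records as a DataFrame in internal column names."""
    rows = [{
        "record_id": r.record_id,
        "compound_id": r.compound_id,
        "assay_id": r.assay_id,
        "target_id": r.target_id or "",
        "standard_type": r.standard_type,
        "standard_relation": r.standard_relation,
        "standard_value": "" if r.standard_value is None
        else repr(r.standard_value) if isinstance(r.standard_value, float)
        else str(r.standard_value),
        "standard_units": r.standard_units or "",
        "activity_comment": r.activity_comment or "",
    } for r in records]
    cols = ["record_id", "compound_id", "assay_id", "target_id",
            "standard_type", "standard_relation", "standard_value",
            "standard_units", "activity_comment"]
    return pd.DataFrame(rows, columns=cols)


def write_activity_table(records: Sequence[ActivityRecord],
                         path: str | Path) -> None:
    """Write records as a TSV readable by :func:`read_activity_table`."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    activity_frame(records).to_csv(path, sep=sep, index=False,
                                   encoding="utf-8")


def read_compound_table(path: str | Path,
                        dialect: str = "internal") -> list[CompoundProfile]:
    df = _rename(_read_frame(path), dialect, CHEMBL_COMPOUND_COLUMNS)
    _require(df, _COMPOUND_MANDATORY, "compound")
    out = []
    for row in df.itertuples(index=False):
        phase = str(getattr(row, "max_phase", "") or "0")
        out.append(CompoundProfile(
            compound_id=str(row.compound_id),
            smiles=str(row.smiles) or None,
            pref_name=str(getattr(row, "pref_name", "")) or None,
            max_phase=int(float(phase)),
        ))
    _check_unique([c.compound_id for c in out], "compound_id")
    return out


def write_compound_table(compounds: Sequence[CompoundProfile],
                         path: str | Path) -> None:
    rows = [{"compound_id": c.compound_id, "smiles": c.smiles or "",
             "pref_name": c.pref_name or "", "max_phase": c.max_phase}
            for c in compounds]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_assay_table(path: str | Path,
                     dialect: str = "internal") -> list[AssayProfile]:
    df = _rename(_read_frame(path), dialect, CHEMBL_ASSAY_COLUMNS)
    _require(df, _ASSAY_MANDATORY, "assay")
    out = []
    for row in df.itertuples(index=False):
        out.append(AssayProfile(
            assay_id=str(row.assay_id),
            description=str(row.description),
            assay_type=str(getattr(row, "assay_type", "")) or "other",
            target_class=str(getattr(row, "target_class", "")),
            organism=str(getattr(row, "organism", "")),
            cell_line=str(getattr(row, "cell_line", "")) or None,
            tissue=str(getattr(row, "tissue", "")) or None,
            bao_format=str(getattr(row, "bao_format", "")) or None,
        ))
    _check_unique([a.assay_id for a in out], "assay_id")
    return out


def write_assay_table(assays: Sequence[AssayProfile],
                      path: str | Path) -> None:
    rows = [{"assay_id": a.assay_id, "description": a.description,
             "assay_type": a.assay_type, "target_class": a.target_class,
             "organism": a.organism, "cell_line": a.cell_line or "",
             "tissue": a.tissue or "", "bao_format": a.bao_format or ""}
            for a in assays]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, encoding="utf-8")


def link_tables(records: Sequence[ActivityRecord],
                compounds: Sequence[CompoundProfile],
                assays: Sequence[AssayProfile]) -> LinkedTable:
    """Join records to compound and assay profiles.

    Records pointing at an unknown compound or assay id are collected
    as orphans and excluded from the resolved view; linking also fills
    each assay's ``n_molecules_seen`` with the count of distinct
    compounds it has records for.
    """
    cmap = {c.compound_id: c for c in compounds}
    amap = {a.assay_id: a for a in assays}
    resolved: list[ActivityRecord] = []
    orphans: list[ActivityRecord] = []
    seen_by_assay: dict[str, set[str]] = {}
    for rec in records:
        if rec.compound_id in cmap and rec.assay_id in amap:
            resolved.append(rec)
            seen_by_assay.setdefault(rec.assay_id, set()).add(rec.compound_id)
        else:
            orphans.append(rec)
    for aid, mols in seen_by_assay.items():
        amap[aid].n_molecules_seen = len(mols)
    return LinkedTable(records=resolved, compounds=cmap, assays=amap,
                       orphans=orphans)
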