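"""Melatonin potency score: heterogeneous activities on one molar scale.

ChEMBL activities come in mixed types (IC50, EC50, Ki, Kd, AC50,
Potency) and units (nM, uM, M, ug/mL, %).  Concentration-typed records
are converted to mol/L and transformed to ``-log10(concentration)``,
the familiar pIC50-style scale on which 6 is 1 uM and 9 is 1 nM.
Non-concentration readouts (percent inhibition etc.) carry no molar
magnitude and yield no score.  Per-compound aggregation averages
within each melatonin receptor subtype first and then across subtypes,
so heavily assayed subtypes do not dominate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .activity_io import ActivityRecord

#: standard_types interpreted as molar concentrations
CONCENTRATION_TYPES = frozenset(
    {"IC50", "EC50", "Ki", "Kd", "AC50", "Potency"})

#: multiplicative factor to mol/L for concentration units
_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}


@dataclass
class PotencyScore:
    """-log10 molar activity of one record.

    ``censored`` records the direction of a non-"=" relation:
    ``at_most`` for ">" (compound is less potent than the bound) and
    ``at_least`` for "<".
    """

    compound_id: str
    assay_id: str
    target_id: Optional[str]
    score: float
    censored: str = "none"  # none | at_most | at_least
    source_type: str = "IC50"
    record_id: Optional[str] = None


@dataclass
class SubtypeAverage:
    """Per-compound melatonin potency averaged over receptor subtypes."""

    compound_id: str
    per_subtype: dict[str, float] = field(default_factory=dict)
    average_score: float = float("nan")
    n_records: int = 0


def potency_score(record: ActivityRecord,
                  mw: Optional[float] = None) -> Optional[PotencyScore]:
    """Transform one record into a potency score, or ``None``.

    Returns ``None`` (with a warning where informative) for
    non-concentration types, missing/non-positive values, unknown
    units, and ug/mL records without a molecular weight.
    """
    if record.standard_type not in CONCENTRATION_TYPES:
        return None
    value = record.standard_value
    if value is None or record.standard_units is None:
        return None
    if value <= 0:
        warnings.warn(
            f"record {record.record_id}: non-positive standard_value "
            f"{value}; no score", stacklevel=2)
        return None
    units = record.standard_units
    if units in _UNIT_TO_MOLAR:
        molar = value * _UNIT_TO_MOLAR[units]
    elif units in ("ug/mL", "ug.mL-1", "µg/mL"):
        if mw is None or mw <= 0:
            warnings.warn(
                f"record {record.record_id}: ug/mL without molecular "
                "weight; no score", stacklevel=2)
            return None
        molar = (value * 1e-3) / mw  # ug/mL -> g/L -> mol/L
    else:
        return None
    censored = "none"
    if record.standard_relation.startswith(">"):
        censored = "at_most"
    elif record.standard_relation.startswith("<"):
        censored = "at_least"
    return PotencyScore(
        compound_id=record.compound_id,
        assay_id=record.assay_id,
        target_id=record.target_id,
        score=-math.log10(molar),
        censored=censored,
        source_type=record.standard_type,
        record_id=record.record_id,
    )


def score_records(records: Iterable[ActivityRecord],
                  mw_by_compound: Optional[Mapping[str, float]] = None,
                  ) -> list[PotencyScore]:
    """Score every record that admits a molar transform."""
    mw_by_compound = mw_by_compound or {}
    out = []
    for rec in records:
        ps = potency_score(rec, mw=mw_by_compound.get(rec.compound_id))
        if ps is not None:
            out.append(ps)
    return out


def aggregate_subtypes(scores: Iterable[PotencyScore],
                       subtype_ids: set[str]) -> dict[str, SubtypeAverage]:
    """Average melatonin potency per compound across receptor subtypes.

    Within each subtype the mean of that subtype's scores is taken
    first; the compound's average is the unweighted mean of the
    subtype means.  Right-censored (">") scores are excluded: they
    bound potency from above and would bias the mean downward by an
    unknown amount.
    """
    if not subtype_ids:
        raise ValueError("subtype_ids must be non-empty")
    per: dict[str, dict[str, list[float]]] = {}
    counts: dict[str, int] = {}
    for s in scores:
        if s.target_id not in subtype_ids or s.censored == "at_most":
            continue
        per.setdefault(s.compound_id, {}).setdefault(
            s.target_id, []).append(s.score)
        counts[s.compound_id] = counts.get(s.compound_id, 0) + 1
    out: dict[str, SubtypeAverage] = {}
    for cid, by_subtype in per.items():
        means = {t: sum(v) / len(v) for t, v in by_subtype.items()}
        out[cid] = SubtypeAverage(
            compound_id=cid,
            per_subtype=means,
            average_score=sum(means.values()) / len(means),
            n_records=counts[cid],
        )
    return out


def subtype_correlation(averages: Mapping[str, SubtypeAverage],
                        min_shared: int = 3) -> pd.DataFrame:
    """Pearson/Spearman correlation between subtype score vectors.

    One row per subtype pair with the number of compounds measured in
    both; coefficients are absent (NaN) below ``min_shared`` shared
    compounds.
    """
    subtypes = sorted({t for a in averages.values() for t in a.per_subtype})
    rows = []
    for t1, t2 in combinations(subtypes, 2):
        x, y = [], []
        for a in averages.values():
            if t1 in a.per_subtype and t2 in a.per_subtype:
                x.append(a.per_subtype[t1])
                y.append(a.per_subtype[t2])
        n = len(x)
        if n >= min_shared:
            pear = stats.pearsonr(x, y).statistic
            spear = stats.spearmanr(x, y).statistic
        else:
            pear = spear = float("nan")
        rows.append({"subtype_a": t1, "subtype_b": t2, "n": n,
                     "pearson_r": pear, "spearman_r": spear})
    return pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "n",
                                       "pearson_r", "spearman_r"])


def write_score_table(scores: Sequence[PotencyScore],
                      path) -> None:
    rows = [{"record_id": s.record_id or "",
             "compound_id": s.compound_id, "target_id": s.target_id or "",
             "assay_id": s.assay_id, "score": s.score,
             "censored": s.censored, "source_type": s.source_type}
            for s in scores]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
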