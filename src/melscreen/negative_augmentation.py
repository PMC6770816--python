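"""Artificial inactive population from GPCR-panel inactivity evidence.

Melatonin-related records are almost all actives, so supervised models
need a constructed negative population.  Following the
evidence-based approach, a compound becomes an eligible negative when
it is inactive in at least ten distinct GPCR-class assays.  "Inactive"
for one record means any of: the activity comment says "Not Active",
its potency score is below 4, or it is right-censored (">") with a
bound score below 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity_io import ActivityRecord, LinkedTable
from .feature_builder import FeatureEncoder
from .potency_scoring import PotencyScore

#: the published negative/positive population sizes used for ratio scaling
REFERENCE_N_NEGATIVES = 60_000
REFERENCE_N_ACTIVE_COMPOUNDS = 1_617


@dataclass
class InactivityRule:
    """Operational definition of an inactive record."""

    comment_marker: str = "not active"
    score_threshold: float = 4.0
    min_gpcr_assays: int = 10


@dataclass
class InactivityEvidence:
    compound_id: str
    n_gpcr_assays_inactive: int
    eligible: bool
    #: one representative inactive record id, for feature encoding
    representative_record_id: Optional[str] = None


def _is_inactive(rec: ActivityRecord, score: Optional[PotencyScore],
                 rule: InactivityRule) -> bool:
    comment = (rec.activity_comment or "").lower()
    if rule.comment_marker in comment:
        return True
    if score is None:
        return False
    if score.censored == "at_most":
        return score.score < rule.score_threshold
    return score.score < rule.score_threshold


def find_inactives(linked: LinkedTable,
                   scores: Iterable[PotencyScore],
                   rule: Optional[InactivityRule] = None,
                   gpcr_class: str = "GPCR") -> list[InactivityEvidence]:
    """Count distinct GPCR assays in which each compound is inactive.

    Eligibility is per distinct assay, not per record: twelve inactive
    records in six assays do not qualify a compound.
    """
    rule = rule or InactivityRule()
    score_by_record: dict[tuple[str, str], PotencyScore] = {
        (s.compound_id, s.assay_id): s for s in scores}
    assays_by_compound: dict[str, set[str]] = {}
    rep: dict[str, str] = {}
    for rec in linked.records:
        assay = linked.assays[rec.assay_id]
        if gpcr_class.lower() not in (assay.target_class or "").lower():
            continue
        sc = score_by_record.get((rec.compound_id, rec.assay_id))
        if _is_inactive(rec, sc, rule):
            assays_by_compound.setdefault(
                rec.compound_id, set()).add(rec.assay_id)
            prev = rep.get(rec.compound_id)
            if prev is None or rec.record_id < prev:
                rep[rec.compound_id] = rec.record_id
    out = [
        InactivityEvidence(
            compound_id=cid,
            n_gpcr_assays_inactive=len(assays),
            eligible=len(assays) >= rule.min_gpcr_assays,
            representative_record_id=rep.get(cid),
        )
        for cid, assays in sorted(assays_by_compound.items())
    ]
    return out


def default_target_count(n_active_compounds: int) -> int:
    """Negative-population size preserving the published class ratio."""
    return round(REFERENCE_N_NEGATIVES * n_active_compounds
                 / REFERENCE_N_ACTIVE_COMPOUNDS)


def augment(validation_rows: pd.DataFrame,
            eligible: Sequence[InactivityEvidence],
            linked: LinkedTable,
            encoder: FeatureEncoder,
            target_count: int,
            seed: int) -> pd.DataFrame:
    """Append sampled inactive rows to the validation set.

    Samples up to ``target_count`` eligible compounds without
    replacement under the given seed and appends one inactive-labeled
    row per compound, encoded from its representative GPCR-panel
    record.  Pre-existing rows are never modified.
    """
    if target_count < 0:
        raise ValueError("target_count must be >= 0")
    pool = sorted((e for e in eligible if e.eligible),
                  key=lambda e: e.compound_id)
    if target_count == 0 or not pool:
        return validation_rows
    if len(pool) < target_count:
        warnings.warn(
            f"only {len(pool)} eligible inactive compounds for a target "
            f"of {target_count}; using all", stacklevel=2)
        chosen = pool
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=target_count, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
    rec_by_id = {r.record_id: r for r in linked.records}
    records = [rec_by_id[e.representative_record_id] for e in chosen
               if e.representative_record_id in rec_by_id]
    new_rows = encoder.encode(records, linked, averages={})
    new_rows["label"] = "inactive"
    new_rows["activity_score"] = encoder.config.inactive_placeholder
    # negatives enter as synthetic rows: give them unique row ids
    new_rows["record_id"] = ["NEG_" + r for r in new_rows["record_id"]]
    return pd.concat([validation_rows, new_rows], ignore_index=True)


def class_balance(rows: pd.DataFrame) -> dict[str, int]:
    counts = rows["label"].value_counts().to_dict()
    return {"active": int(counts.get("active", 0)),
            "inactive": int(counts.get("inactive", 0))}


def write_roster(evidence: Sequence[InactivityEvidence], path) -> None:
    pd.DataFrame([{
        "compound_id": e.compound_id,
        "n_gpcr_assays_inactive": e.n_gpcr_assays_inactive,
        "eligible": e.eligible,
    } for e in evidence]).to_csv(path, sep="\t", index=False)
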