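"""Database-wide virtual screening and melatonin-score hit calling.

The trained bundle is applied to every encodable record in the
universe and aggregated per compound.  A compound's final melatonin
score is its measured averaged potency score when one exists;
otherwise it is predicted as countRatio x mean predicted score, which
damps compounds the classifier calls active inconsistently while
preserving the regression magnitude.  Hits are compounds with a
melatonin score strictly greater than 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .feature_builder import FeatureSchema
from .rf_models import (CompoundPrediction, ModelBundle, aggregate_compound,
                        predict_records)

DEFAULT_HIT_THRESHOLD = 4.0


@dataclass
class ScreenResult:
    compound_id: str
    pref_name: Optional[str]
    count_ratio: float
    mean_predicted_score: float
    actual_score: Optional[float]
    melatonin_score: float
    is_hit: bool
    n_records: int


def combine_scores(count_ratio: float, mean_predicted_score: float) -> float:
    """Predicted melatonin score when no measured score exists."""
    return count_ratio * mean_predicted_score


def screen(bundle: ModelBundle,
           universe_rows: pd.DataFrame,
           schema: FeatureSchema,
           actual_scores: Mapping[str, float],
           pref_names: Optional[Mapping[str, str]] = None,
           hit_threshold: float = DEFAULT_HIT_THRESHOLD,
           batch_size: int = 50_000) -> list[ScreenResult]:
    """Score the full record universe and call hits per compound.

    ``actual_scores`` maps compound_id to the measured averaged
    melatonin potency score; where present it overrides the model
    combination entirely.  Records are scored in batches so very large
    universes stream through.
    """
    if universe_rows.empty:
        raise ValueError("empty screening universe")
    pref_names = pref_names or {}
    pred_parts = []
    for start in range(0, len(universe_rows), batch_size):
        chunk = universe_rows.iloc[start:start + batch_size]
        pred_parts.append(predict_records(bundle, chunk, schema))
    preds = pd.concat(pred_parts, ignore_index=True)
    results = []
    for cp in aggregate_compound(preds, actual_scores):
        if cp.actual_score is not None and np.isfinite(cp.actual_score):
            score = float(cp.actual_score)
        else:
            score = combine_scores(cp.count_ratio, cp.mean_predicted_score)
        results.append(ScreenResult(
            compound_id=cp.compound_id,
            pref_name=pref_names.get(cp.compound_id),
            count_ratio=cp.count_ratio,
            mean_predicted_score=cp.mean_predicted_score,
            actual_score=cp.actual_score,
            melatonin_score=score,
            is_hit=score > hit_threshold,
            n_records=cp.n_occasions,
        ))
    return results


def score_histogram(results: Sequence[ScreenResult],
                    bin_width: float = 0.5) -> pd.DataFrame:
    """Melatonin-score distribution as fixed-width bins.

    Counts are conserved: the bin counts sum to the number of
    compounds screened.
    """
    if not results:
        raise ValueError("no screen results to bin")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    scores = np.array([r.melatonin_score for r in results])
    lo = np.floor(scores.min() / bin_width) * bin_width
    hi = np.floor(scores.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(scores, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def hits(results: Iterable[ScreenResult]) -> list[ScreenResult]:
    return [r for r in results if r.is_hit]


def named_drug_hits(results: Iterable[ScreenResult]) -> pd.DataFrame:
    """Hits restricted to compounds with a drug name, best first."""
    rows = [{
        "compound_id": r.compound_id,
        "pref_name": r.pref_name,
        "melatonin_score": r.melatonin_score,
        "count_ratio": r.count_ratio,
        "actual_score": r.actual_score,
        "n_records": r.n_records,
    } for r in results if r.is_hit and r.pref_name]
    frame = pd.DataFrame(rows, columns=[
        "compound_id", "pref_name", "melatonin_score", "count_ratio",
        "actual_score", "n_records"])
    return frame.sort_values(["melatonin_score", "compound_id"],
                             ascending=[False, True],
                             ignore_index=True)


def results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "compound_id": r.compound_id,
        "pref_name": r.pref_name or "",
        "count_ratio": r.count_ratio,
        "mean_predicted_score": r.mean_predicted_score,
        "actual_score": "" if r.actual_score is None else r.actual_score,
        "melatonin_score": r.melatonin_score,
        "is_hit": r.is_hit,
        "n_records": r.n_records,
    } for r in results])
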