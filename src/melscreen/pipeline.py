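"""End-to-end melatonin virtual-screening pipeline.

Chains the stages: score normalization -> subtype averaging ->
60-variable encoding -> negative augmentation -> 80/20 split ->
random-forest training -> held-out evaluation -> database-wide
screening -> hit calling -> cardiovascular cross-filtering.  All
randomness (split, sampling, forests) derives from one seed, so a run
is a pure function of (input tables, seed) and output tables are
byte-identical across repeated runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import (activity_io, cardio_selection, feature_builder,
               negative_augmentation, potency_scoring, rf_models,
               virtual_screening)
from .activity_io import LinkedTable
from .synthetic_chembl import (SUBTYPE_IDS, SyntheticConfig,
                               SyntheticUniverse, generate, truth_report)


@dataclass
class PipelineResult:
    linked: LinkedTable
    scores: list
    averages: dict
    validation_rows: pd.DataFrame
    split_plan: rf_models.SplitPlan
    bundle: rf_models.ModelBundle
    evaluation: dict
    screen_results: list
    cv_hits: list
    cv_summary: cardio_selection.CVSummary
    truth_metrics: Optional[dict] = None
    class_balance: dict = field(default_factory=dict)


def _derive_seeds(seed: int) -> dict[str, int]:
    base = int(seed) % (2 ** 31 - 1000)
    return {"augment": base + 11, "split": base + 22, "model": base + 33}


def run_pipeline(linked: LinkedTable,
                 seed: int,
                 subtype_ids: Sequence[str] = SUBTYPE_IDS,
                 label_threshold: float = 4.0,
                 hit_threshold: float = 4.0,
                 chembl_threshold: float = 4.5,
                 target_negative_count: Optional[int] = None,
                 universe: Optional[SyntheticUniverse] = None,
                 ) -> PipelineResult:
    """Run every stage on a linked table; see the module docstring."""
    seeds = _derive_seeds(seed)

    # 1. potency scores (molecular weights for ug/mL conversion)
    mw = {}
    for comp in linked.compounds.values():
        if comp.smiles:
            try:
                mw[comp.compound_id] = feature_builder.compute_descriptors(
                    comp.smiles)["molecular_weight"]
            except ValueError:
                pass
    scores = potency_scoring.score_records(linked.records, mw)
    averages = potency_scoring.aggregate_subtypes(scores, set(subtype_ids))

    # 2. validation set: every record of a melatonin-measured compound
    config = feature_builder.FeatureConfig(
        subtype_ids=tuple(subtype_ids), label_threshold=label_threshold)
    schema = feature_builder.build_schema(config)
    encoder = feature_builder.FeatureEncoder(schema, config).fit(linked)
    mel_compounds = set(averages)
    val_records = [r for r in linked.records
                   if r.compound_id in mel_compounds]
    rows = encoder.encode(val_records, linked, averages)

    # 3. negative augmentation from GPCR inactivity evidence
    evidence = negative_augmentation.find_inactives(linked, scores)
    n_active_compounds = sum(
        1 for a in averages.values() if a.average_score > label_threshold)
    target = (negative_augmentation.default_target_count(n_active_compounds)
              if target_negative_count is None else target_negative_count)
    rows = negative_augmentation.augment(
        rows, evidence, linked, encoder, target, seeds["augment"])
    balance = negative_augmentation.class_balance(rows)

    # 4. split / train / evaluate
    plan = rf_models.split(rows, seeds["split"])
    train_rows = rows[rows["record_id"].isin(set(plan.train_record_ids))]
    test_rows = rows[rows["record_id"].isin(set(plan.test_record_ids))]
    bundle = rf_models.train(train_rows, schema, seeds["model"],
                             split_plan=plan)
    evaluation = rf_models.evaluate(bundle, test_rows, schema)

    # 5. screen the whole universe
    universe_rows = encoder.encode(linked.records, linked, averages)
    actual = {cid: a.average_score for cid, a in averages.items()}
    pref = {c.compound_id: c.pref_name
            for c in linked.compounds.values() if c.pref_name}
    screen_results = virtual_screening.screen(
        bundle, universe_rows, schema, actual, pref,
        hit_threshold=hit_threshold)

    # 6. cardiovascular cross-filtering
    cardio_selection.flag_cardiovascular(linked.assays.values())
    cv_hits, cv_summary = cardio_selection.select_cv_hits(
        screen_results, scores, linked,
        chembl_threshold=chembl_threshold,
        melatonin_threshold=hit_threshold)

    truth_metrics = None
    if universe is not None:
        truth_metrics = truth_report(universe.truth, screen_results,
                                     cv_hits, hit_threshold)
    return PipelineResult(
        linked=linked, scores=scores, averages=averages,
        validation_rows=rows, split_plan=plan, bundle=bundle,
        evaluation=evaluation, screen_results=screen_results,
        cv_hits=cv_hits, cv_summary=cv_summary,
        truth_metrics=truth_metrics, class_balance=balance)


def run_synthetic_pipeline(config: SyntheticConfig,
                           target_negative_count: Optional[int] = None,
                           ) -> PipelineResult:
    """Generate a synthetic universe and run the pipeline on it."""
    uni = generate(config)
    linked = activity_io.link_tables(uni.records, uni.compounds, uni.assays)
    return run_pipeline(linked, seed=config.seed, universe=uni,
                        target_negative_count=target_negative_count)


def write_outputs(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write every result table; returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    _w("potency_scores.tsv",
       lambda p: potency_scoring.write_score_table(result.scores, p))
    _w("screen_results.tsv",
       lambda p: virtual_screening.results_frame(
           result.screen_results).to_csv(p, sep="\t", index=False))
    _w("named_drug_hits.tsv",
       lambda p: virtual_screening.named_drug_hits(
           result.screen_results).to_csv(p, sep="\t", index=False))
    _w("score_histogram.tsv",
       lambda p: virtual_screening.score_histogram(
           result.screen_results).to_csv(p, sep="\t", index=False))
    in_vivo, in_vitro = cardio_selection.split_by_category(result.cv_hits)
    _w("cv_hits_in_vivo.tsv",
       lambda p: in_vivo.to_csv(p, sep="\t", index=False))
    _w("cv_hits_in_vitro.tsv",
       lambda p: in_vitro.to_csv(p, sep="\t", index=False))
    if result.cv_hits:
        g = cardio_selection.interaction_graph(result.cv_hits)
        _w("cv_graph.graphml",
           lambda p: cardio_selection.write_graph(
               g, p, out / "cv_edges.tsv"))
    eval_json = {k: v for k, v in result.evaluation.items()
                 if k != "compound_predictions"}
    summary = {
        "evaluation": eval_json,
        "class_balance": result.class_balance,
        "cv_summary": {"n_records": result.cv_summary.n_records,
                       "n_assays": result.cv_summary.n_assays,
                       "n_molecules": result.cv_summary.n_molecules},
        "n_hits": sum(1 for r in result.screen_results if r.is_hit),
        "truth_metrics": result.truth_metrics,
    }
    _w("summary.json",
       lambda p: p.write_text(json.dumps(summary, indent=1, sort_keys=True)))
    return written
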