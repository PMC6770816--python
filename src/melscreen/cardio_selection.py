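"""Cardiovascular cross-filtering of melatonin-active compounds.

Assays are flagged cardiovascular by a configurable keyword/tissue
rule (the matched term is recorded per assay for audit).  A CV hit is
one activity record whose assay is cardiovascular, whose measured
potency score in that assay exceeds 4.5, and whose compound's
melatonin screen score exceeds 4 — both comparisons strict.  Hits are
reported per record with distinct record/assay/molecule summary
counts, split into in-vivo and in-vitro tables, and exported as a
bipartite assay-molecule interaction graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .activity_io import AssayProfile, LinkedTable
from .potency_scoring import PotencyScore
from .virtual_screening import ScreenResult

DEFAULT_CV_KEYWORDS = (
    "heart", "cardiac", "aort", "coronary", "arrhythmi",
    "blood pressure", "hypertens", "vasoconstrict", "vasodilat",
    "atria", "ventric", "vascular",
)

DEFAULT_CHEMBL_THRESHOLD = 4.5
DEFAULT_MELATONIN_THRESHOLD = 4.0


@dataclass
class CVHit:
    record_id: str
    compound_id: str
    pref_name: Optional[str]
    assay_id: str
    assay_description: str
    assay_category: str  # in_vivo | in_vitro
    chembl_score: float
    melatonin_score: float
    n_molecules_seen: int


@dataclass
class CVSummary:
    n_records: int
    n_assays: int
    n_molecules: int


def flag_cardiovascular(assays: Iterable[AssayProfile],
                        keywords: Sequence[str] = DEFAULT_CV_KEYWORDS,
                        ) -> list[AssayProfile]:
    """Set ``is_cardiovascular`` from description/tissue keywords.

    Matching is case-insensitive substring; the first matching term is
    stored on the assay so the flagging is auditable.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    out = []
    for assay in assays:
        haystack = " ".join(
            filter(None, (assay.description, assay.tissue))).lower()
        match = next((k for k in keywords if k.lower() in haystack), None)
        assay.is_cardiovascular = match is not None
        assay.cv_matched_term = match
        out.append(assay)
    return out


def _assay_category(assay: AssayProfile) -> str:
    """In-vivo when the assay is organism-level without a cell line."""
    text = (assay.description or "").lower()
    if "in vivo" in text or (assay.tissue and not assay.cell_line):
        return "in_vivo"
    return "in_vitro"


def select_cv_hits(results: Sequence[ScreenResult],
                   scores: Iterable[PotencyScore],
                   linked: LinkedTable,
                   chembl_threshold: float = DEFAULT_CHEMBL_THRESHOLD,
                   melatonin_threshold: float = DEFAULT_MELATONIN_THRESHOLD,
                   ) -> tuple[list[CVHit], CVSummary]:
    """Cross-filter the screen against cardiovascular assay records.

    One CV hit per record with (assay flagged cardiovascular) AND
    (measured potency score in that assay > chembl_threshold) AND
    (compound melatonin score > melatonin_threshold).
    """
    mel_score = {r.compound_id: r.melatonin_score for r in results}
    name = {r.compound_id: r.pref_name for r in results}
    by_record_id: dict[str, PotencyScore] = {}
    by_pair: dict[tuple[str, str], list[PotencyScore]] = {}
    for s in scores:
        if s.record_id is not None:
            by_record_id[s.record_id] = s
        by_pair.setdefault((s.compound_id, s.assay_id), []).append(s)
    hits: list[CVHit] = []
    for rec in linked.records:
        assay = linked.assays[rec.assay_id]
        if not assay.is_cardiovascular:
            continue
        ms = mel_score.get(rec.compound_id)
        if ms is None or not ms > melatonin_threshold:
            continue
        own = by_record_id.get(rec.record_id)
        candidates = ([own] if own is not None
                      else by_pair.get((rec.compound_id, rec.assay_id), []))
        passing = [s.score for s in candidates
                   if s.score > chembl_threshold]
        if passing:
            hits.append(CVHit(
                record_id=rec.record_id,
                compound_id=rec.compound_id,
                pref_name=name.get(rec.compound_id),
                assay_id=rec.assay_id,
                assay_description=assay.description,
                assay_category=_assay_category(assay),
                chembl_score=max(passing),
                melatonin_score=ms,
                n_molecules_seen=assay.n_molecules_seen,
            ))
    summary = CVSummary(
        n_records=len({h.record_id for h in hits}),
        n_assays=len({h.assay_id for h in hits}),
        n_molecules=len({h.compound_id for h in hits}),
    )
    return hits, summary


def split_by_category(hits: Sequence[CVHit],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-vivo and in-vitro hit tables."""
    frame = hits_frame(hits)
    in_vivo = frame[frame["assay_category"] == "in_vivo"].reset_index(
        drop=True)
    in_vitro = frame[frame["assay_category"] == "in_vitro"].reset_index(
        drop=True)
    return in_vivo, in_vitro


def hits_frame(hits: Sequence[CVHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "record_id": h.record_id,
        "compound_id": h.compound_id,
        "pref_name": h.pref_name or "",
        "assay_id": h.assay_id,
        "assay_description": h.assay_description,
        "assay_category": h.assay_category,
        "chembl_score": h.chembl_score,
        "melatonin_score": h.melatonin_score,
        "n_molecules_seen": h.n_molecules_seen,
    } for h in hits], columns=[
        "record_id", "compound_id", "pref_name", "assay_id",
        "assay_description", "assay_category", "chembl_score",
        "melatonin_score", "n_molecules_seen"])


def interaction_graph(hits: Sequence[CVHit]) -> nx.Graph:
    """Bipartite assay-molecule graph of the CV hits.

    Molecule nodes carry their drug name when one exists; unnamed
    molecules get ``anonymous=True`` so renderers can hide the raw
    registry id, mirroring the display rule of the hit diagram.
    Parallel records for the same (molecule, assay) pair collapse to
    one edge carrying the best ChEMBL score.
    """
    g = nx.Graph()
    for h in hits:
        a_node = "assay:" + h.assay_id
        m_node = "mol:" + h.compound_id
        g.add_node(a_node, bipartite="assay",
                   description=h.assay_description,
                   category=h.assay_category)
        g.add_node(m_node, bipartite="molecule",
                   label=h.pref_name or "",
                   anonymous=h.pref_name is None,
                   melatonin_score=h.melatonin_score)
        prev = g.get_edge_data(a_node, m_node)
        best = max(h.chembl_score,
                   prev["chembl_score"]) if prev else h.chembl_score
        g.add_edge(a_node, m_node, chembl_score=best)
    return g


def write_graph(g: nx.Graph, graphml_path, edgelist_path) -> None:
    nx.write_graphml(g, graphml_path)
    rows = [{"assay": u if u.startswith("assay:") else v,
             "molecule": v if u.startswith("assay:") else u,
             "chembl_score": d["chembl_score"]}
            for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["assay", "molecule", "chembl_score"]).to_csv(
        edgelist_path, sep="\t", index=False)
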