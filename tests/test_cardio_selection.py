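import networkx as nx
import numpy as np
import pytest

from melscreen.activity_io import (ActivityRecord, AssayProfile,
                                   CompoundProfile, link_tables)
from melscreen.cardio_selection import (CVHit, flag_cardiovascular,
                                        hits_frame, interaction_graph,
                                        select_cv_hits, split_by_category)
from melscreen.potency_scoring import PotencyScore
from melscreen.virtual_screening import ScreenResult


def _screen(cid, score, name=None):
    return ScreenResult(compound_id=cid, pref_name=name, count_ratio=1.0,
                        mean_predicted_score=score, actual_score=score,
                        melatonin_score=score, is_hit=score > 4.0,
                        n_records=1)


class TestFlagging:
    def test_aortic_ring_description_is_flagged(self):
        assay = AssayProfile("a1", description=(
            "Inhibition of rat aortic ring contraction"))
        out = flag_cardiovascular([assay])[0]
        assert out.is_cardiovascular
        assert out.cv_matched_term == "aort"

    def test_serotonin_binding_not_flagged(self):
        assay = AssayProfile("a1", description="Binding affinity at 5-HT2C")
        assert not flag_cardiovascular([assay])[0].is_cardiovascular

    def test_tissue_field_can_flag(self):
        assay = AssayProfile("a1", description="Contractility model",
                             tissue="heart")
        assert flag_cardiovascular([assay])[0].is_cardiovascular

    def test_matching_is_case_insensitive(self):
        assay = AssayProfile("a1", description="EFFECT ON BLOOD PRESSURE")
        assert flag_cardiovascular([assay])[0].is_cardiovascular

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError):
            flag_cardiovascular([AssayProfile("a1", description="x")],
                                keywords=())

    def test_planted_cv_assays_all_flagged(self, small_universe):
        flagged = flag_cardiovascular(small_universe.assays)
        got = {a.assay_id for a in flagged if a.is_cardiovascular}
        planted = {aid for aid, cat in
                   small_universe.truth.assay_category.items()
                   if cat == "cv"}
        assert got == planted
        assert len(planted) == small_universe.config.n_cv_assays


def _toy_cv_setting():
    """Six records: exactly 3 pass both thresholds, in 2 CV assays
    with 2 molecules (hand-enumerated)."""
    assays = flag_cardiovascular([
        AssayProfile("cv1", description="Effect on blood pressure"),
        AssayProfile("cv2", description="Cardiac contractility assay"),
        AssayProfile("nc1", description="Binding at 5-HT2C"),
    ])
    compounds = [CompoundProfile(c, smiles="CCO")
                 for c in ("m1", "m2", "m3")]
    spec = [  # record, compound, assay, chembl_score
        ("r1", "m1", "cv1", 5.0),   # pass (mel 6.0)
        ("r2", "m1", "cv2", 6.0),   # pass
        ("r3", "m2", "cv1", 5.5),   # pass (mel 4.5)
        ("r4", "m2", "cv2", 4.5),   # fail: chembl == threshold, strict
        ("r5", "m3", "cv1", 7.0),   # fail: melatonin score 3.0 < 4
        ("r6", "m1", "nc1", 9.0),   # fail: not a CV assay
    ]
    records = [ActivityRecord(r, c, a, standard_type="IC50",
                              standard_value=10 ** (9 - s),
                              standard_units="nM")
               for r, c, a, s in spec]
    linked = link_tables(records, compounds, assays)
    scores = [PotencyScore(c, a, None, s)
              for _, c, a, s in [(r, c, a, s) for r, c, a, s in spec]]
    results = [_screen("m1", 6.0, name="DrugA"), _screen("m2", 4.5),
               _screen("m3", 3.0)]
    return results, scores, linked


class TestSelection:
    def test_hand_enumerated_toy_summary(self):
        results, scores, linked = _toy_cv_setting()
        hits, summary = select_cv_hits(results, scores, linked)
        assert {h.record_id for h in hits} == {"r1", "r2", "r3"}
        assert (summary.n_records, summary.n_assays, summary.n_molecules) \
            == (3, 2, 2)

    def test_infinite_thresholds_empty_result(self):
        results, scores, linked = _toy_cv_setting()
        hits, summary = select_cv_hits(results, scores, linked,
                                       chembl_threshold=np.inf,
                                       melatonin_threshold=np.inf)
        assert hits == []
        assert summary.n_records == 0

    def test_exact_chembl_threshold_excluded(self):
        results, scores, linked = _toy_cv_setting()
        hits, _ = select_cv_hits(results, scores, linked)
        assert "r4" not in {h.record_id for h in hits}

    def test_matches_brute_force_triple_loop(self):
        results, scores, linked = _toy_cv_setting()
        hits, _ = select_cv_hits(results, scores, linked)
        mel = {r.compound_id: r.melatonin_score for r in results}
        score_map = {(s.compound_id, s.assay_id): s.score for s in scores}
        expected = set()
        for rec in linked.records:
            for aid, assay in linked.assays.items():
                if rec.assay_id != aid or not assay.is_cardiovascular:
                    continue
                s = score_map.get((rec.compound_id, aid))
                if s is None or not s > 4.5:
                    continue
                if mel.get(rec.compound_id, -1) > 4.0:
                    expected.add(rec.record_id)
        assert {h.record_id for h in hits} == expected

    def test_monotone_in_both_thresholds(self):
        results, scores, linked = _toy_cv_setting()
        prev = None
        for t in (4.0, 4.5, 5.0, 5.5, 6.0, 7.0):
            hits, summary = select_cv_hits(results, scores, linked,
                                           chembl_threshold=t)
            if prev is not None:
                assert summary.n_records <= prev
            prev = summary.n_records

    def test_category_split_partitions_hits(self, default_pipeline):
        in_vivo, in_vitro = split_by_category(default_pipeline.cv_hits)
        assert len(in_vivo) + len(in_vitro) \
            == len(default_pipeline.cv_hits)


class TestGraph:
    def _hits(self, spec):
        return [CVHit(record_id=f"r{i}", compound_id=m, pref_name=name,
                      assay_id=a, assay_description="d",
                      assay_category="in_vitro", chembl_score=5.0,
                      melatonin_score=6.0, n_molecules_seen=1)
                for i, (m, a, name) in enumerate(spec)]

    def test_three_hits_two_by_two(self):
        g = interaction_graph(self._hits(
            [("m1", "a1", "A"), ("m1", "a2", "A"), ("m2", "a2", None)]))
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3

    def test_single_hit(self):
        g = interaction_graph(self._hits([("m1", "a1", None)]))
        assert (g.number_of_nodes(), g.number_of_edges()) == (2, 1)

    def test_unnamed_molecules_are_anonymous(self):
        g = interaction_graph(self._hits([("m1", "a1", None),
                                          ("m2", "a1", "DrugB")]))
        assert g.nodes["mol:m1"]["anonymous"]
        assert not g.nodes["mol:m2"]["anonymous"]
        assert g.nodes["mol:m2"]["label"] == "DrugB"

    def test_bipartite_no_same_side_edges(self, default_pipeline):
        g = interaction_graph(default_pipeline.cv_hits)
        for u, v in g.edges:
            assert {g.nodes[u]["bipartite"], g.nodes[v]["bipartite"]} \
                == {"assay", "molecule"}

    def test_handshake_lemma(self, default_pipeline):
        g = interaction_graph(default_pipeline.cv_hits)
        assert sum(dict(g.degree).values()) == 2 * g.number_of_edges()

    def test_graphml_round_trip(self, tmp_path, default_pipeline):
        from melscreen.cardio_selection import write_graph
        g = interaction_graph(default_pipeline.cv_hits)
        write_graph(g, tmp_path / "g.graphml", tmp_path / "e.tsv")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
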