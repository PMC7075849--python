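import numpy as np
import pandas as pd
import pytest

from weaksup.data_model import (
    Candidate,
    CandidateSchema,
    ContextCollection,
    ContextNode,
    LabelingFunction,
    Span,
    apply_lfs,
    dictionary_lf_generator,
    extract_candidates,
    lf_statistics,
    load_contexts,
    pattern_lf_template,
    save_contexts,
    worker_lf_generator,
)


def make_cdr_collection():
    """One document, two sentences with tagged chemical/disease mentions."""
    doc = ContextNode(id="d1", ctype="document", parent_id=None, text="")
    s1_text = "Magnesium causes myasthenia gravis in rare cases."
    s2_text = "Aspirin treats headache effectively."
    s1 = ContextNode(id="s1", ctype="sentence", parent_id="d1", text=s1_text)
    s2 = ContextNode(id="s2", ctype="sentence", parent_id="d1", text=s2_text)
    spans = [
        Span("s1", 0, 9, "chemical"),
        Span("s1", 17, 34, "disease"),
        Span("s2", 0, 7, "chemical"),
        Span("s2", 15, 23, "disease"),
    ]
    return ContextCollection([doc, s1, s2], spans)


class TestContexts:
    def test_small_hierarchy_forms_forest(self):
        coll = make_cdr_collection()
        assert len(coll) == 3
        assert len(coll.sentences()) == 2

    def test_dangling_parent_is_an_integrity_error(self):
        doc = ContextNode(id="d1", ctype="document", parent_id=None, text="")
        orphan = ContextNode(id="s1", ctype="sentence", parent_id="missing", text="x")
        with pytest.raises(ValueError, match="missing"):
            ContextCollection([doc, orphan])

    def test_span_beyond_sentence_is_rejected(self):
        doc = ContextNode(id="d1", ctype="document", parent_id=None, text="")
        sent = ContextNode(id="s1", ctype="sentence", parent_id="d1", text="short")
        with pytest.raises(ValueError, match="exceeds"):
            ContextCollection([doc, sent], [Span("s1", 0, 99, "chemical")])

    def test_random_hierarchy_round_trips_field_for_field(self, tmp_path):
        rng = np.random.default_rng(7)
        nodes, spans = [], []
        for d in range(10):
            nodes.append(ContextNode(id=f"d{d}", ctype="document", parent_id=None, text=""))
            for s in range(4):
                text = "".join(rng.choice(list("abcde fgh")) for _ in range(30))
                sid = f"d{d}s{s}"
                nodes.append(ContextNode(id=sid, ctype="sentence", parent_id=f"d{d}", text=text, meta={"k": str(s)}))
                start = int(rng.integers(0, 15))
                spans.append(Span(sid, start, start + 5, "chemical"))
        coll = ContextCollection(nodes, spans)
        path = tmp_path / "ctx.jsonl"
        save_contexts(coll, path)
        assert load_contexts(path) == coll

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"id": "d1", "ctype": "document", "parent_id": null, "text": ""}\nnot json\n')
        with pytest.raises(ValueError, match="line 2"):
            load_contexts(path)


class TestExtraction:
    def test_tagged_pair_sentences_yield_two_candidates(self):
        cands = extract_candidates(
            make_cdr_collection(), CandidateSchema("chemical", "disease")
        )
        assert len(cands) == 2
        assert cands[0].span_texts() == ("Magnesium", "myasthenia gravis")

    def test_unknown_entity_type_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="gene"):
            extract_candidates(make_cdr_collection(), CandidateSchema("gene", "disease"))

    def test_sentence_without_spans_yields_nothing(self):
        doc = ContextNode(id="d1", ctype="document", parent_id=None, text="")
        sent = ContextNode(id="s1", ctype="sentence", parent_id="d1", text="nothing here")
        tagged = ContextNode(id="s2", ctype="sentence", parent_id="d1", text="Magnesium hurts")
        coll = ContextCollection(
            [doc, sent, tagged],
            [Span("s2", 0, 9, "chemical"), Span("s2", 10, 15, "disease")],
        )
        cands = extract_candidates(coll, CandidateSchema("chemical", "disease"))
        assert {c.sentence_id for c in cands} == {"s2"}

    def test_candidate_count_matches_brute_force_pairing(self):
        rng = np.random.default_rng(3)
        doc = ContextNode(id="d1", ctype="document", parent_id=None, text="")
        nodes, spans = [doc], []
        expected = 0
        for s in range(8):
            k, d = rng.integers(0, 4, size=2)
            expected += int(k) * int(d)
            text = "x" * 100
            sid = f"s{s}"
            nodes.append(ContextNode(id=sid, ctype="sentence", parent_id="d1", text=text))
            offset = 0
            for _ in range(k):
                spans.append(Span(sid, offset, offset + 3, "chemical"))
                offset += 5
            for _ in range(d):
                spans.append(Span(sid, offset, offset + 3, "disease"))
                offset += 5
        if expected == 0:  # keep the oracle non-trivial
            spans.append(Span("s0", 90, 93, "chemical"))
            spans.append(Span("s0", 94, 97, "disease"))
            expected += 1
        coll = ContextCollection(nodes, spans)
        cands = extract_candidates(coll, CandidateSchema("chemical", "disease"))
        assert len(cands) == expected

    def test_candidate_ids_are_stable_across_reruns(self):
        coll = make_cdr_collection()
        schema = CandidateSchema("chemical", "disease")
        first = [c.id for c in extract_candidates(coll, schema)]
        second = [c.id for c in extract_candidates(coll, schema)]
        assert first == second


class TestApply:
    def test_always_abstaining_lf_has_empty_column(self):
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))
        lf = LabelingFunction("silent", lambda c: 0)
        L = apply_lfs([lf], cands)
        assert L.sparse.nnz == 0

    def test_causes_pattern_votes_positive_when_chemical_first(self):
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))
        lf = pattern_lf_template("causes", r"\bcauses\b")
        L = apply_lfs([lf], cands).toarray()
        # sentence 1 contains "causes" between the mentions; sentence 2 does not
        assert L[0, 0] == 1
        assert L[1, 0] == 0

    def test_application_is_pure_and_order_independent(self):
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))
        lfs = [
            pattern_lf_template("causes", r"\bcauses\b"),
            pattern_lf_template("treats", r"\btreats\b", first_span_votes=(-1, 1)),
        ]
        a = apply_lfs(lfs, cands)
        b = apply_lfs(lfs, cands)
        assert a == b

    def test_strict_mode_aborts_with_candidate_id(self):
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))

        def broken(c):
            raise KeyError("boom")

        lfs = [LabelingFunction("broken", broken)]
        with pytest.raises(RuntimeError, match=cands[0].id):
            apply_lfs(lfs, cands, on_error="strict")
        lenient = apply_lfs(lfs, cands, on_error="lenient")
        assert lenient.sparse.nnz == 0


class TestStatistics:
    def test_single_lf_has_no_overlap_or_conflict(self):
        stats = lf_statistics(np.array([[1], [0], [-1]]))
        assert stats.loc[0, "overlap"] == 0
        assert stats.loc[0, "conflict"] == 0
        assert stats.loc[0, "coverage"] == pytest.approx(2 / 3)

    def test_identical_full_columns_overlap_without_conflict(self):
        stats = lf_statistics(np.array([[1, 1], [-1, -1], [1, 1]]))
        assert (stats["overlap"] == 1).all()
        assert (stats["conflict"] == 0).all()

    def test_hand_enumerated_three_by_two(self):
        # rows: (+1,-1) both vote, disagree; (+1,0) only LF0; (0,0) nobody
        V = np.array([[1, -1], [1, 0], [0, 0]])
        stats = lf_statistics(V, gold=np.array([1, 1, -1]))
        assert stats["coverage"].tolist() == pytest.approx([2 / 3, 1 / 3])
        assert stats["overlap"].tolist() == pytest.approx([1 / 3, 1 / 3])
        assert stats["conflict"].tolist() == pytest.approx([1 / 3, 1 / 3])
        assert stats["accuracy"].tolist() == pytest.approx([1.0, 0.0])

    def test_conflict_le_overlap_le_coverage_on_random_matrices(self, random_vote_matrix):
        stats = lf_statistics(random_vote_matrix)
        assert (stats["conflict"] <= stats["overlap"] + 1e-12).all()
        assert (stats["overlap"] <= stats["coverage"] + 1e-12).all()
        assert ((stats[["coverage", "overlap", "conflict"]] >= 0).all()).all()
        assert ((stats[["coverage", "overlap", "conflict"]] <= 1).all()).all()

    def test_gold_length_mismatch_is_a_shape_error(self):
        with pytest.raises(ValueError, match="shape"):
            lf_statistics(np.array([[1, -1]]), gold=np.array([1, 1]))


class TestTemplates:
    def test_pattern_template_matches_hand_written_equivalent(self):
        rng = np.random.default_rng(11)
        doc = ContextNode(id="d1", ctype="document", parent_id=None, text="")
        nodes, spans = [doc], []
        for i in range(100):
            connector = rng.choice(["causes", "reduces", "treats", "and"])
            chem, dis = "drugx", "illy"
            if rng.random() < 0.5:
                text = f"{chem} {connector} {dis}"
                spans.append(Span(f"s{i}", 0, len(chem), "chemical"))
                spans.append(Span(f"s{i}", len(text) - len(dis), len(text), "disease"))
            else:
                text = f"{dis} {connector} {chem}"
                spans.append(Span(f"s{i}", len(text) - len(chem), len(text), "chemical"))
                spans.append(Span(f"s{i}", 0, len(dis), "disease"))
            nodes.append(ContextNode(id=f"s{i}", ctype="sentence", parent_id="d1", text=text))
        coll = ContextCollection(nodes, spans)
        cands = extract_candidates(coll, CandidateSchema("chemical", "disease"))
        template = pattern_lf_template("causes", r"\bcauses\b")

        def hand_written(c):
            between = c.between_text()
            if "causes" not in between:
                return 0
            return 1 if c.spans[0].start < c.spans[1].start else -1

        hand = LabelingFunction("hand", hand_written)
        L = apply_lfs([template, hand], cands).toarray()
        np.testing.assert_array_equal(L[:, 0], L[:, 1])
        assert (L[:, 0] != 0).any() and (L[:, 0] == 0).any()

    def test_impossible_pattern_always_abstains(self):
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))
        lf = pattern_lf_template("never", r"\bz{50}\b")
        assert apply_lfs([lf], cands).sparse.nnz == 0

    def test_invalid_pattern_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="pattern"):
            pattern_lf_template("bad", r"([unclosed")

    def test_dictionary_generator_creates_one_lf_per_subset(self):
        lfs = dictionary_lf_generator(
            {
                "causes": ({("magnesium", "myasthenia gravis")}, 1),
                "treats": ({("aspirin", "headache")}, -1),
            }
        )
        assert len(lfs) == 2
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))
        L = apply_lfs(lfs, cands).toarray()
        np.testing.assert_array_equal(L, [[1, 0], [0, -1]])

    def test_empty_dictionary_map_yields_no_lfs(self):
        assert dictionary_lf_generator({}) == []

    def test_pair_in_both_subsets_creates_conflict(self):
        key = {("magnesium", "myasthenia gravis")}
        lfs = dictionary_lf_generator({"a": (key, 1), "b": (key, -1)})
        cands = extract_candidates(make_cdr_collection(), CandidateSchema("chemical", "disease"))
        stats = lf_statistics(apply_lfs(lfs, cands))
        assert (stats["conflict"] > 0).any()

    def test_worker_generator_pivots_the_vote_table(self):
        rng = np.random.default_rng(5)
        cand_ids = [f"c{i}" for i in range(30)]
        records = []
        for w in range(20):
            graded = rng.choice(30, size=10, replace=False)
            for c in graded:
                records.append((f"w{w:02d}", cand_ids[c], int(rng.choice([-1, 1]))))
        table = pd.DataFrame(records, columns=["worker_id", "candidate_id", "vote"])
        lfs = worker_lf_generator(table)
        assert len(lfs) == 20
        cands = [Candidate(id=cid, spans=(Span("s", 0, 1), Span("s", 1, 2))) for cid in cand_ids]
        L = apply_lfs(lfs, cands)
        wide = table.pivot(index="candidate_id", columns="worker_id", values="vote").fillna(0)
        wide = wide.reindex(index=cand_ids, columns=sorted(table["worker_id"].unique()))
        np.testing.assert_array_equal(L.toarray(), wide.to_numpy(dtype=np.int8))

    def test_worker_votes_must_be_plus_minus_one(self):
        with pytest.raises(ValueError, match="votes"):
            worker_lf_generator(pd.DataFrame(
                [("w1", "c1", 0)], columns=["worker_id", "candidate_id", "vote"]
            ))
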