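"""Context hierarchy, candidates, and labeling functions.

Input text is organized as a small forest: documents contain sentences;
sentences carry tagged entity spans (e.g. chemical and disease mentions).
A *candidate* is an ordered pair of spans in the same sentence — the data
point a labeling function votes on.  Labeling functions map a candidate to
+1, -1, or 0 (abstain); applying a list of them to a candidate list yields
the sparse label matrix consumed by the generative model.

Conventions: character offsets are 0-based half-open; abstentions are
encoded as 0 in memory and as absent entries on disk; candidate ids are
derived from sentence id and span offsets so reruns are stable.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import LabelMatrix

__all__ = [
    "ContextNode",
    "Span",
    "Candidate",
    "LabelingFunction",
    "ContextCollection",
    "CandidateSchema",
    "load_contexts",
    "save_contexts",
    "extract_candidates",
    "save_candidates",
    "load_candidates",
    "apply_lfs",
    "lf_statistics",
    "pattern_lf_template",
    "dictionary_lf_generator",
    "worker_lf_generator",
]

logger = logging.getLogger(__name__)

_CTYPES = ("document", "sentence")


@dataclass(frozen=True)
class ContextNode:
    """One node of the document -> sentence forest."""

    id: str
    ctype: str
    parent_id: str | None
    text: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ctype not in _CTYPES:
            raise ValueError(f"unknown ctype {self.ctype!r}")


@dataclass(frozen=True)
class Span:
    """A tagged character span inside a sentence; offsets are 0-based,
    start inclusive, end exclusive."""

    sentence_id: str
    start: int
    end: int
    entity_type: str | None = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")

    def text_in(self, sentence_text: str) -> str:
        return sentence_text[self.start : self.end]


@dataclass(frozen=True)
class Candidate:
    """An ordered pair of spans in one sentence, plus that sentence's text
    so labeling functions are self-contained."""

    id: str
    spans: tuple[Span, Span]
    sentence_text: str = field(default="", compare=False)

    @property
    def sentence_id(self) -> str:
        return self.spans[0].sentence_id

    def span_texts(self) -> tuple[str, str]:
        return tuple(s.text_in(self.sentence_text) for s in self.spans)

    def between_text(self) -> str:
        """Text strictly between the two spans (empty if they overlap)."""
        a, b = sorted(self.spans, key=lambda s: s.start)
        return self.sentence_text[min(a.end, b.start) : b.start]

    def first_span_index(self) -> int:
        """0 if spans[0] starts first in the sentence, else 1."""
        return 0 if self.spans[0].start <= self.spans[1].start else 1


@dataclass(frozen=True)
class LabelingFunction:
    """A named, deterministic map Candidate -> {-1, 0, +1} (0 = abstain)."""

    name: str
    body: callable

    def __call__(self, candidate: Candidate) -> int:
        vote = self.body(candidate)
        if vote not in (-1, 0, 1):
            raise ValueError(
                f"labeling function {self.name!r} returned {vote!r}; "
                "votes must lie in {-1,0,+1}"
            )
        return int(vote)


class ContextCollection:
    """A validated forest of documents and sentences with tagged spans."""

    def __init__(self, nodes: list[ContextNode], spans: list[Span] | None = None):
        self.nodes = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("node ids must be unique within a collection")
        self.spans: list[Span] = list(spans or [])
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.ctype == "sentence":
                if node.parent_id is None or node.parent_id not in self.nodes:
                    raise ValueError(
                        f"sentence {node.id!r} references missing document "
                        f"{node.parent_id!r}"
                    )
                if self.nodes[node.parent_id].ctype != "document":
                    raise ValueError(f"sentence {node.id!r} parent is not a document")
            elif node.parent_id is not None:
                raise ValueError(f"document {node.id!r} must not have a parent")
        for span in self.spans:
            sent = self.nodes.get(span.sentence_id)
            if sent is None or sent.ctype != "sentence":
                raise ValueError(f"span references missing sentence {span.sentence_id!r}")
            if span.end > len(sent.text):
                raise ValueError(
                    f"span [{span.start}, {span.end}) exceeds sentence "
                    f"{span.sentence_id!r} of length {len(sent.text)}"
                )

    def sentences(self) -> list[ContextNode]:
        return [n for n in self.nodes.values() if n.ctype == "sentence"]

    def spans_in(self, sentence_id: str) -> list[Span]:
        return [s for s in self.spans if s.sentence_id == sentence_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContextCollection):
            return NotImplemented
        return self.nodes == other.nodes and sorted(
            self.spans, key=lambda s: (s.sentence_id, s.start, s.end)
        ) == sorted(other.spans, key=lambda s: (s.sentence_id, s.start, s.end))


def load_contexts(path) -> ContextCollection:
    """Read a JSONL context file: one node per line with id, ctype,
    parent_id, text, meta, and (for sentences) embedded spans."""
    nodes: list[ContextNode] = []
    spans: list[Span] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                node = ContextNode(
                    id=record["id"],
                    ctype=record["ctype"],
                    parent_id=record.get("parent_id"),
                    text=record["text"],
                    meta=record.get("meta", {}),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            nodes.append(node)
            for raw in record.get("spans", ()):
                spans.append(
                    Span(
                        sentence_id=node.id,
                        start=raw["start"],
                        end=raw["end"],
                        entity_type=raw.get("entity_type"),
                    )
                )
    return ContextCollection(nodes, spans)


def save_contexts(collection: ContextCollection, path) -> None:
    with open(path, "w") as handle:
        for node in collection.nodes.values():
            record = {
                "id": node.id,
                "ctype": node.ctype,
                "parent_id": node.parent_id,
                "text": node.text,
                "meta": node.meta,
            }
            if node.ctype == "sentence":
                record["spans"] = [
                    {"start": s.start, "end": s.end, "entity_type": s.entity_type}
                    for s in collection.spans_in(node.id)
                ]
            handle.write(json.dumps(record) + "\n")


@dataclass(frozen=True)
class CandidateSchema:
    """Which entity-type pair forms a candidate; scope is the co-occurrence
    unit (same sentence by default, optionally whole document)."""

    type_a: str
    type_b: str
    scope: str = "sentence"

    def __post_init__(self):
        if self.scope not in ("sentence", "document"):
            raise ValueError(f"unknown scope {self.scope!r}")


def extract_candidates(
    collection: ContextCollection, schema: CandidateSchema
) -> list[Candidate]:
    """One candidate per ordered (type_a, type_b) span pair within scope.

    Candidate ids are content-derived (sentence id + offsets), so repeated
    extraction yields identical ids.
    """
    known_types = {s.entity_type for s in collection.spans}
    for t in (schema.type_a, schema.type_b):
        if t not in known_types:
            raise ValueError(f"entity type {t!r} not present in the collection")
    if schema.scope == "document":
        raise NotImplementedError("document-scope extraction is not enabled by default")
    out: list[Candidate] = []
    for sentence in sorted(collection.sentences(), key=lambda s: s.id):
        spans = collection.spans_in(sentence.id)
        firsts = [s for s in spans if s.entity_type == schema.type_a]
        seconds = [s for s in spans if s.entity_type == schema.type_b]
        for a in sorted(firsts, key=lambda s: (s.start, s.end)):
            for b in sorted(seconds, key=lambda s: (s.start, s.end)):
                cid = f"{sentence.id}:{a.start}-{a.end}:{b.start}-{b.end}"
                out.append(Candidate(id=cid, spans=(a, b), sentence_text=sentence.text))
    return out


def save_candidates(candidates: list[Candidate], path) -> None:
    with open(path, "w") as handle:
        for cand in candidates:
            record = {
                "id": cand.id,
                "sentence_id": cand.sentence_id,
                "spans": [
                    {"start": s.start, "end": s.end, "entity_type": s.entity_type}
                    for s in cand.spans
                ],
            }
            handle.write(json.dumps(record) + "\n")


def load_candidates(path, collection: ContextCollection) -> list[Candidate]:
    """Rehydrate candidates against their context collection (the sentence
    text is not serialized with the candidate)."""
    out: list[Candidate] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                sentence = collection.nodes[record["sentence_id"]]
                spans = tuple(
                    Span(
                        sentence_id=record["sentence_id"],
                        start=s["start"],
                        end=s["end"],
                        entity_type=s.get("entity_type"),
                    )
                    for s in record["spans"]
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            out.append(Candidate(id=record["id"], spans=spans, sentence_text=sentence.text))
    return out


def apply_lfs(
    lfs: list[LabelingFunction],
    candidates: list[Candidate],
    on_error: str = "lenient",
) -> LabelMatrix:
    """Apply every labeling function to every candidate.

    ``on_error="lenient"`` converts labeling-function exceptions into
    abstentions (with a warning log), so one brittle pattern cannot kill a
    batch; ``"strict"`` re-raises with the candidate id.  The result is a
    pure function of (lfs, candidates) regardless of execution order.
    """
    if on_error not in ("lenient", "strict"):
        raise ValueError(f"unknown error policy {on_error!r}")
    names = [lf.name for lf in lfs]
    if len(set(names)) != len(names):
        raise ValueError("labeling function names must be unique")
    rows, cols, data = [], [], []
    for i, cand in enumerate(candidates):
        for j, lf in enumerate(lfs):
            try:
                vote = lf(cand)
            except Exception as exc:  # noqa: BLE001 - user code boundary
                if on_error == "strict":
                    raise RuntimeError(
                        f"labeling function {lf.name!r} failed on candidate "
                        f"{cand.id!r}: {exc}"
                    ) from exc
                logger.warning(
                    "labeling function %r failed on candidate %r (%s); abstaining",
                    lf.name,
                    cand.id,
                    exc,
                )
                vote = 0
            if vote != 0:
                rows.append(i)
                cols.append(j)
                data.append(vote)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(candidates), len(lfs)), dtype=np.int8
    )
    return LabelMatrix(mat, row_ids=[c.id for c in candidates], col_names=names)


def lf_statistics(L: LabelMatrix, gold=None) -> pd.DataFrame:
    """Per-LF coverage, overlap, conflict, and (with gold) empirical accuracy.

    coverage: fraction of rows where the LF votes; overlap: votes alongside
    at least one other LF; conflict: votes against at least one other LF.
    conflict <= overlap <= coverage always holds.
    """
    V = L.toarray() if isinstance(L, LabelMatrix) else np.asarray(L)
    m, n = V.shape
    names = L.col_names if isinstance(L, LabelMatrix) else list(range(n))
    voted = V != 0
    votes_per_row = voted.sum(axis=1)
    pos = (V == 1).sum(axis=1)
    neg = (V == -1).sum(axis=1)
    stats = {}
    cov = voted.mean(axis=0) if m else np.zeros(n)
    overlap = (voted & (votes_per_row > 1)[:, None]).mean(axis=0) if m else np.zeros(n)
    # an LF conflicts on a row iff someone voted the opposite sign there
    conflict_pos = (V == 1) & (neg > 0)[:, None]
    conflict_neg = (V == -1) & (pos > 0)[:, None]
    conflict = (conflict_pos | conflict_neg).mean(axis=0) if m else np.zeros(n)
    stats = pd.DataFrame(
        {"coverage": cov, "overlap": overlap, "conflict": conflict}, index=names
    )
    if gold is not None:
        gold = np.asarray(gold)
        if gold.shape != (m,):
            raise ValueError(f"gold has shape {gold.shape}, expected ({m},)")
        if not np.isin(gold, (-1, 1)).all():
            raise ValueError("gold labels must lie in {-1,+1}")
        correct = (V == gold[:, None]) & voted
        with np.errstate(invalid="ignore"):
            acc = correct.sum(axis=0) / voted.sum(axis=0)
        stats["accuracy"] = acc
    return stats


# ---------------------------------------------------------------------------
# declarative templates and generators
# ---------------------------------------------------------------------------

def pattern_lf_template(
    name: str,
    pattern: str,
    first_span_votes: tuple[int, int] = (1, -1),
    flags: int = re.IGNORECASE,
) -> LabelingFunction:
    """A labeling function that searches the text between the two spans.

    On a match, the vote depends on which span comes first in the sentence:
    ``first_span_votes[0]`` when spans[0] precedes spans[1], else
    ``first_span_votes[1]``.  No match means abstain.
    """
    try:
        compiled = re.compile(pattern, flags)
    except re.error as exc:
        raise ValueError(f"invalid pattern for {name!r}: {exc}") from exc
    if not all(v in (-1, 1) for v in first_span_votes):
        raise ValueError("votes must lie in {-1,+1}")

    def body(cand: Candidate) -> int:
        if not compiled.search(cand.between_text()):
            return 0
        return first_span_votes[cand.first_span_index()]

    return LabelingFunction(name=name, body=body)


def _normalize_key(text: str) -> str:
    return " ".join(text.casefold().split())


def dictionary_lf_generator(
    subsets: dict[str, tuple[set, int]]
) -> list[LabelingFunction]:
    """One labeling function per dictionary subset.

    Each subset maps a name to ``(pair_keys, vote)`` where ``pair_keys`` is
    a set of (entity_a, entity_b) surface-string pairs; keys are case-folded
    and whitespace-normalized before lookup.  The LF votes its subset's
    label when the candidate's normalized span texts are in the set,
    otherwise it abstains.
    """
    lfs: list[LabelingFunction] = []
    seen: set[str] = set()
    for subset_name, (pairs, vote) in subsets.items():
        if subset_name in seen:
            raise ValueError(f"duplicate subset name {subset_name!r}")
        seen.add(subset_name)
        if vote not in (-1, 1):
            raise ValueError(f"subset {subset_name!r}: vote must be -1 or +1")
        normalized = {tuple(_normalize_key(t) for t in pair) for pair in pairs}

        def body(cand: Candidate, _keys=frozenset(normalized), _vote=vote) -> int:
            key = tuple(_normalize_key(t) for t in cand.span_texts())
            return _vote if key in _keys else 0

        lfs.append(LabelingFunction(name=f"dict_{subset_name}", body=body))
    return lfs


def worker_lf_generator(votes) -> list[LabelingFunction]:
    """One labeling function per crowd worker.

    ``votes`` is a DataFrame (or records) with columns worker_id,
    candidate_id, vote in {-1,+1}.  Each worker's LF votes their recorded
    label and abstains on candidates they did not grade.
    """
    frame = pd.DataFrame(votes, columns=["worker_id", "candidate_id", "vote"]) if not isinstance(votes, pd.DataFrame) else votes
    bad = frame.loc[~frame["vote"].isin([-1, 1])]
    if len(bad):
        raise ValueError(f"votes must lie in {{-1,+1}}; found {sorted(bad['vote'].unique())}")
    lfs = []
    for worker_id, group in frame.groupby("worker_id", sort=True):
        table = dict(zip(group["candidate_id"], group["vote"].astype(int)))

        def body(cand: Candidate, _table=table) -> int:
            return _table.get(cand.id, 0)

        lfs.append(LabelingFunction(name=f"worker_{worker_id}", body=body))
    return lfs
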