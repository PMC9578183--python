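"""Entity-annotated abstracts, candidate sentences, and abstract-level splits.

Candidate extraction turns an abstract annotated with typed entity mentions
(Disease / Gene / Compound) into *candidate sentences*: sentences that
co-mention a type-compatible entity pair for one of the four relationship
classes (metaedges) of interest — Disease-associates-Gene (DaG),
Compound-treats-Disease (CtD), Compound-binds-Gene (CbG) and
Gene-interacts-Gene (GiG).

Input is the PubTator text export dialect: blocks of ``PMID|t|title``,
``PMID|a|abstract`` and tab-separated annotation lines, separated by blank
lines.  Character offsets are 0-based, end-exclusive and index into the
concatenation ``title + " " + abstract``.

No linguistic parser is bundled: tokens are whitespace-derived unless the
caller (or the synthetic corpus generator) supplies pre-computed tokens,
part-of-speech tags and dependency edges.
"""

from __future__ import annotations

import csv
import io
import itertools
import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import ConfigurationError, PubtatorParseError
from .seeding import unit_uniform

logger = logging.getLogger(__name__)

#: Ordered entity-type signature of each in-scope metaedge.
EDGE_TYPE_SIGNATURES: dict[str, tuple[str, str]] = {
    "DaG": ("Disease", "Gene"),
    "CtD": ("Compound", "Disease"),
    "CbG": ("Compound", "Gene"),
    "GiG": ("Gene", "Gene"),
}

METAEDGES = tuple(EDGE_TYPE_SIGNATURES)

SPLITS = ("train", "tune", "test")

# Sentence boundary: sentence-final punctuation, whitespace, then an
# uppercase letter or digit.  Synthetic corpora are generated pre-segmented,
# so nothing downstream depends on this rule's linguistic quality.
_SENTENCE_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


@dataclass(frozen=True)
class EntityAnnotation:
    """One typed entity mention with a normalized graph identifier."""

    document_id: str
    start: int
    end: int
    surface_text: str
    entity_type: str
    normalized_id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"annotation span [{self.start}, {self.end}) is empty or inverted"
            )


@dataclass
class AnnotatedAbstract:
    """A title + abstract with its entity annotations."""

    document_id: str
    title_text: str
    abstract_text: str
    annotations: list[EntityAnnotation] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return f"{self.title_text} {self.abstract_text}"


@dataclass
class CandidateSentence:
    """A sentence co-mentioning one type-compatible entity pair.

    ``mention_pair`` offsets are re-based to the sentence; ``pos_tags`` and
    ``dependency_edges`` are optional pre-supplied annotation layers.
    ``dependency_edges`` entries are ``(head index, dependent index,
    relation)`` over token indices.
    """

    candidate_id: str
    document_id: str
    sentence_text: str
    tokens: list[str]
    mention_pair: tuple[EntityAnnotation, EntityAnnotation]
    edge_type: str
    pos_tags: list[str] | None = None
    dependency_edges: list[tuple[int, int, str]] | None = None
    split: str | None = None
    gold_label: str | None = None  # "positive" | "negative" | "unlabeled"

    def __post_init__(self):
        if self.edge_type not in EDGE_TYPE_SIGNATURES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        if self.pos_tags is not None and len(self.pos_tags) != len(self.tokens):
            raise ValueError("pos_tags must align with tokens")

    @property
    def pair_ids(self) -> tuple[str, str]:
        return (self.mention_pair[0].normalized_id, self.mention_pair[1].normalized_id)

    def token_char_starts(self) -> list[int]:
        starts, cursor = [], 0
        for tok in self.tokens:
            idx = self.sentence_text.find(tok, cursor)
            if idx < 0:  # token not locatable; fall back to cursor
                idx = cursor
            starts.append(idx)
            cursor = idx + len(tok)
        return starts

    def mention_token_spans(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Token-index spans (start, end exclusive) of the two mentions."""
        starts = self.token_char_starts()
        spans = []
        for ann in self.mention_pair:
            lo = len(self.tokens)
            hi = 0
            for i, (s, tok) in enumerate(zip(starts, self.tokens)):
                e = s + len(tok)
                if s < ann.end and e > ann.start:  # overlap
                    lo = min(lo, i)
                    hi = max(hi, i + 1)
            if hi <= lo:  # mention does not align with any token
                lo, hi = 0, 0
            spans.append((lo, hi))
        return spans[0], spans[1]

    def tokens_between_mentions(self) -> list[str]:
        (a_lo, a_hi), (b_lo, b_hi) = self.mention_token_spans()
        if a_lo > b_lo:
            (a_lo, a_hi), (b_lo, b_hi) = (b_lo, b_hi), (a_lo, a_hi)
        return self.tokens[a_hi:b_lo]


@dataclass
class SplitAssignment:
    """Abstract-level train/tune/test assignment."""

    assignment: dict[str, str]
    seed: int
    probabilities: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def __post_init__(self):
        _validate_probabilities(self.probabilities)

    def __getitem__(self, document_id: str) -> str:
        return self.assignment[document_id]

    def fractions(self) -> dict[str, float]:
        n = max(len(self.assignment), 1)
        return {s: sum(v == s for v in self.assignment.values()) / n for s in SPLITS}


def _validate_probabilities(probabilities) -> None:
    if len(probabilities) != 3 or any(p < 0 for p in probabilities):
        raise ConfigurationError("probabilities must be 3 nonnegative fractions")
    if abs(sum(probabilities) - 1.0) > 1e-12:
        raise ConfigurationError(
            f"split probabilities must sum to 1, got {sum(probabilities)!r}"
        )


# ---------------------------------------------------------------------------
# PubTator dialect
# ---------------------------------------------------------------------------

def parse_pubtator(stream) -> list[AnnotatedAbstract]:
    """Parse a PubTator export into :class:`AnnotatedAbstract` records.

    ``stream`` may be a string or any iterable of lines.  Annotations whose
    span does not reproduce their surface text are dropped with a warning;
    structurally malformed blocks raise :class:`PubtatorParseError`.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]

    abstracts: list[AnnotatedAbstract] = []
    block: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.strip() == "":
            if block:
                abstracts.append(_parse_block(block))
                block = []
        else:
            block.append((lineno, line))
    if block:
        abstracts.append(_parse_block(block))
    return abstracts


def _parse_block(block: list[tuple[int, str]]) -> AnnotatedAbstract:
    lineno, first = block[0]
    parts = first.split("|", 2)
    if len(parts) != 3 or parts[1] != "t":
        raise PubtatorParseError(
            "expected 'PMID|t|title' line", line_number=lineno
        )
    doc_id, _, title = parts
    abstract_text = ""
    ann_lines = block[1:]
    if ann_lines:
        lineno2, second = ann_lines[0]
        parts2 = second.split("|", 2)
        if len(parts2) == 3 and parts2[1] == "a":
            if parts2[0] != doc_id:
                raise PubtatorParseError(
                    "abstract line PMID differs from title line",
                    document_id=doc_id, line_number=lineno2,
                )
            abstract_text = parts2[2]
            ann_lines = ann_lines[1:]

    doc = AnnotatedAbstract(doc_id, title, abstract_text)
    for lineno3, line in ann_lines:
        fields = line.split("\t")
        if len(fields) < 6:
            raise PubtatorParseError(
                f"annotation line has {len(fields)} fields, expected >= 6",
                document_id=doc_id, line_number=lineno3,
            )
        pmid, start_s, end_s, text, etype, norm_id = fields[:6]
        if pmid != doc_id:
            raise PubtatorParseError(
                "annotation PMID differs from block PMID",
                document_id=doc_id, line_number=lineno3,
            )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise PubtatorParseError(
                "annotation offsets are not integers",
                document_id=doc_id, line_number=lineno3,
            ) from None
        if not (0 <= start < end <= len(doc.full_text)) or (
            doc.full_text[start:end] != text
        ):
            logger.warning(
                "dropping annotation with span/text mismatch "
                "(document=%s, line=%d, span=[%d,%d), text=%r)",
                doc_id, lineno3, start, end, text,
            )
            continue
        doc.annotations.append(
            EntityAnnotation(doc_id, start, end, text, etype, norm_id)
        )
    return doc


def write_pubtator(abstracts: Iterable[AnnotatedAbstract]) -> str:
    """Serialize abstracts back to the PubTator text dialect."""
    out = io.StringIO()
    for doc in abstracts:
        out.write(f"{doc.document_id}|t|{doc.title_text}\n")
        out.write(f"{doc.document_id}|a|{doc.abstract_text}\n")
        for ann in doc.annotations:
            out.write(
                f"{doc.document_id}\t{ann.start}\t{ann.end}\t"
                f"{ann.surface_text}\t{ann.entity_type}\t{ann.normalized_id}\n"
            )
        out.write("\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Filtering and candidate extraction
# ---------------------------------------------------------------------------

def filter_entities_to_graph(abstracts, graph) -> list[AnnotatedAbstract]:
    """Keep only annotations whose normalized id is a node of ``graph``.

    The document set is unchanged; abstracts may end up annotation-free.
    """
    filtered = []
    for doc in abstracts:
        kept = [a for a in doc.annotations if graph.has_node(a.normalized_id)]
        filtered.append(replace(doc, annotations=list(kept)))
    return filtered


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences in ``text`` (0-based, end-exclusive)."""
    spans, start = [], 0
    for m in _SENTENCE_BOUNDARY.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def extract_candidates(
    abstract: AnnotatedAbstract,
    edge_type: str,
    *,
    sentence_spans: Sequence[tuple[int, int]] | None = None,
) -> list[CandidateSentence]:
    """All type-compatible co-mention candidates of ``edge_type``.

    One candidate is emitted per sentence per unordered type-compatible
    mention-pair occurrence; sentences with fewer than two annotations yield
    none.  Overlapping mention pairs are skipped with a warning.  Tokens are
    whitespace-derived; POS tags and dependency edges are left unset (they
    are pre-supplied annotation layers, not parser output).
    """
    if edge_type not in EDGE_TYPE_SIGNATURES:
        raise ConfigurationError(f"unknown edge type {edge_type!r}")
    type_a, type_b = EDGE_TYPE_SIGNATURES[edge_type]
    text = abstract.full_text
    if sentence_spans is None:
        sentence_spans = segment_sentences(text)

    candidates: list[CandidateSentence] = []
    counter = itertools.count()
    for s_lo, s_hi in sentence_spans:
        in_sent = [a for a in abstract.annotations if s_lo <= a.start and a.end <= s_hi]
        if len(in_sent) < 2:
            continue
        sentence_text = text[s_lo:s_hi]
        if type_a == type_b:
            mentions = [a for a in in_sent if a.entity_type == type_a]
            pairs = list(itertools.combinations(mentions, 2))
            # unordered; canonicalize by lexicographic normalized id
            pairs = [
                (m1, m2) if m1.normalized_id <= m2.normalized_id else (m2, m1)
                for m1, m2 in pairs
            ]
        else:
            first = [a for a in in_sent if a.entity_type == type_a]
            second = [a for a in in_sent if a.entity_type == type_b]
            pairs = list(itertools.product(first, second))
        for m1, m2 in pairs:
            if m1.start < m2.end and m2.start < m1.end:
                logger.warning(
                    "skipping candidate with overlapping mentions "
                    "(document=%s, spans [%d,%d) and [%d,%d))",
                    abstract.document_id, m1.start, m1.end, m2.start, m2.end,
                )
                continue
            rebased = tuple(
                replace(m, start=m.start - s_lo, end=m.end - s_lo) for m in (m1, m2)
            )
            k = next(counter)
            candidates.append(
                CandidateSentence(
                    candidate_id=f"{abstract.document_id}:{edge_type}:{k}",
                    document_id=abstract.document_id,
                    sentence_text=sentence_text,
                    tokens=sentence_text.split(),
                    mention_pair=rebased,  # type: ignore[arg-type]
                    edge_type=edge_type,
                )
            )
    return candidates


def assign_splits(
    document_ids: Iterable[str],
    probabilities: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign each abstract a train/tune/test split.

    The split of one document is a pure function of (document id, seed,
    probabilities): documents keep their split when the corpus grows.
    """
    _validate_probabilities(probabilities)
    p_train, p_tune, _ = probabilities
    assignment = {}
    for doc_id in document_ids:
        u = unit_uniform(seed, "split", doc_id)
        if u < p_train:
            assignment[doc_id] = "train"
        elif u < p_train + p_tune:
            assignment[doc_id] = "tune"
        else:
            assignment[doc_id] = "test"
    return SplitAssignment(assignment, seed=seed, probabilities=probabilities)


def apply_splits(candidates, splits: SplitAssignment) -> None:
    """Propagate abstract-level splits onto candidates in place."""
    for cand in candidates:
        cand.split = splits[cand.document_id]


# ---------------------------------------------------------------------------
# Candidate TSV serialization
# ---------------------------------------------------------------------------

_CAND_COLUMNS = [
    "candidate_id", "document_id", "edge_type", "split", "gold_label",
    "sentence_text", "tokens", "pos_tags", "dependency_edges",
    "m1_start", "m1_end", "m1_text", "m1_type", "m1_id",
    "m2_start", "m2_end", "m2_text", "m2_type", "m2_id",
]


def write_candidates(candidates: Iterable[CandidateSentence], path) -> None:
    """One row per candidate; token/POS/dependency layers JSON-encoded."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CAND_COLUMNS)
        for c in candidates:
            m1, m2 = c.mention_pair
            writer.writerow([
                c.candidate_id, c.document_id, c.edge_type,
                c.split or "", c.gold_label or "",
                c.sentence_text,
                json.dumps(c.tokens),
                json.dumps(c.pos_tags),
                json.dumps(c.dependency_edges),
                m1.start, m1.end, m1.surface_text, m1.entity_type, m1.normalized_id,
                m2.start, m2.end, m2.surface_text, m2.entity_type, m2.normalized_id,
            ])


def read_candidates(path) -> list[CandidateSentence]:
    candidates = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            deps = json.loads(row["dependency_edges"])
            candidates.append(
                CandidateSentence(
                    candidate_id=row["candidate_id"],
                    document_id=row["document_id"],
                    sentence_text=row["sentence_text"],
                    tokens=json.loads(row["tokens"]),
                    pos_tags=json.loads(row["pos_tags"]),
                    dependency_edges=(
                        None if deps is None else [tuple(e) for e in deps]
                    ),
                    mention_pair=(
                        EntityAnnotation(
                            row["document_id"], int(row["m1_start"]),
                            int(row["m1_end"]), row["m1_text"],
                            row["m1_type"], row["m1_id"],
                        ),
                        EntityAnnotation(
                            row["document_id"], int(row["m2_start"]),
                            int(row["m2_end"]), row["m2_text"],
                            row["m2_type"], row["m2_id"],
                        ),
                    ),
                    edge_type=row["edge_type"],
                    split=row["split"] or None,
                    gold_label=row["gold_label"] or None,
                )
            )
    return candidates
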