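"""Concept extraction from free-text notes.

Three-step pipeline: (i) split a note into sub-texts on sentence
punctuation and newlines, (ii) classify each sub-text into one of four
context categories — patient/family x affirmation/negation, with neutral
text counting as affirmation — using sentence-scope cue lexicons, and
(iii) in patient-affirmation sub-texts only, exactly match thesaurus
terms at word boundaries and keep the most precise concepts.

Matching semantics: a concept matches when one of its normalized terms
occurs as a whole-token subsequence of the normalized sub-text.  Longer
terms claim their tokens first; overlap ties break by earliest start,
then lexicographic concept id; tokens are consumed at most once per
scan.  The surviving concept set is then reduced with
:meth:`~edlos.thesaurus.ConceptThesaurus.most_precise` so that an
ancestor never co-occurs with its matched descendant.

Stay-level output is binary presence: the union over patient-affirmation
sub-texts, with no counts kept.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path

from .config import CueConfig
from .thesaurus import ConceptThesaurus, normalize_term

__all__ = [
    "ContextLabel",
    "ConceptMention",
    "split_subtexts",
    "classify_context",
    "match_concepts",
    "extract_stay_concepts",
    "extract_mentions",
    "write_mentions_csv",
    "write_stay_concepts_json",
    "read_stay_concepts_json",
]

_SPLIT_RE = re.compile(r"[.!?;\n]+")
_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


@dataclass(frozen=True)
class ContextLabel:
    """Subject (patient/family) and polarity (affirmation/negation)."""

    subject: str  # "patient" | "family"
    polarity: str  # "affirmation" | "negation"

    def __post_init__(self):
        if self.subject not in ("patient", "family"):
            raise ValueError(f"bad subject {self.subject!r}")
        if self.polarity not in ("affirmation", "negation"):
            raise ValueError(f"bad polarity {self.polarity!r}")

    @property
    def is_patient_affirmation(self) -> bool:
        return self.subject == "patient" and self.polarity == "affirmation"


@dataclass(frozen=True)
class ConceptMention:
    stay_id: str
    sentence_index: int
    concept_id: str
    context: ContextLabel
    matched_term: str


def split_subtexts(text: str) -> list[str]:
    """Split free text into sub-texts on sentence punctuation (. ! ? ;) and newlines.

    Sub-texts are stripped and empty ones dropped; together they cover
    all non-delimiter characters in order.
    """
    return [part.strip() for part in _SPLIT_RE.split(text) if part.strip()]


def _contains_cue(tokens: tuple[str, ...], cue_tokens: list[tuple[str, ...]]) -> bool:
    for cue in cue_tokens:
        k = len(cue)
        if any(tokens[i : i + k] == cue for i in range(len(tokens) - k + 1)):
            return True
    return False


def _tokenize(text: str) -> tuple[str, ...]:
    return tuple(_TOKEN_RE.findall(normalize_term(text)))


def classify_context(subtext: str, cues: CueConfig) -> ContextLabel:
    """Classify a sub-text into one of the four context categories.

    Family and negation fire independently on whole-token cue matches;
    a cue-free sub-text is patient-affirmation.
    """
    tokens = _tokenize(subtext)
    neg = [_tokenize(c) for c in cues.negation_cues]
    fam = [_tokenize(c) for c in cues.family_cues]
    return ContextLabel(
        subject="family" if _contains_cue(tokens, fam) else "patient",
        polarity="negation" if _contains_cue(tokens, neg) else "affirmation",
    )


def _term_token_index(th: ConceptThesaurus):
    """Tokenized term index keyed by first token, memoized per thesaurus."""
    cached = getattr(th, "_edlos_match_index", None)
    if cached is None:
        by_first: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
        for term, cid in th.term_index.items():
            term_tokens = tuple(_TOKEN_RE.findall(term))
            if term_tokens:
                by_first.setdefault(term_tokens[0], []).append((term_tokens, cid, term))
        cached = by_first
        th._edlos_match_index = by_first
    return cached


def _candidate_matches(
    tokens: tuple[str, ...], th: ConceptThesaurus
) -> list[tuple[int, int, str, str]]:
    """All (start, n_tokens, concept_id, term) term occurrences in the token list."""
    by_first = _term_token_index(th)
    out = []
    for i, tok in enumerate(tokens):
        for term_tokens, cid, term in by_first.get(tok, ()):
            if tokens[i : i + len(term_tokens)] == term_tokens:
                out.append((i, len(term_tokens), cid, term))
    return out


def match_concepts(
    subtext: str, th: ConceptThesaurus, *, with_terms: bool = False
) -> set[str] | dict[str, str]:
    """Exactly match thesaurus terms in a sub-text and keep the most precise concepts.

    Returns the concept-id set, or a ``{concept_id: matched_term}`` map
    when ``with_terms`` is true.
    """
    tokens = _tokenize(subtext)
    candidates = _candidate_matches(tokens, th)
    # longest term first, then earliest start, then concept id; consume tokens once
    candidates.sort(key=lambda m: (-m[1], m[0], m[2]))
    taken = [False] * len(tokens)
    accepted: dict[str, str] = {}
    for start, n, cid, term in candidates:
        if any(taken[start : start + n]):
            continue
        for j in range(start, start + n):
            taken[j] = True
        accepted.setdefault(cid, term)
    kept = th.most_precise(set(accepted))
    if with_terms:
        return {cid: accepted[cid] for cid in sorted(kept)}
    return kept


def extract_mentions(
    stay_id: str,
    sentences: list[str],
    th: ConceptThesaurus,
    cues: CueConfig,
) -> list[ConceptMention]:
    """Full per-sentence extraction with context labels (all four categories)."""
    mentions = []
    for idx, sentence in enumerate(sentences):
        label = classify_context(sentence, cues)
        for cid, term in match_concepts(sentence, th, with_terms=True).items():
            mentions.append(ConceptMention(stay_id, idx, cid, label, term))
    return mentions


def extract_stay_concepts(
    notes: list[dict],
    th: ConceptThesaurus,
    cues: CueConfig,
) -> set[str]:
    """Stay-level binary concept presence.

    ``notes`` are note documents of one stay (each a mapping with a
    ``sentences`` list; a bare list of sentences is also accepted).
    Only sub-texts classified patient-affirmation contribute; concepts
    found solely in negated or family-related sub-texts never appear.
    """
    found: set[str] = set()
    for note in notes:
        sentences = note["sentences"] if isinstance(note, dict) else note
        for raw in sentences:
            for sub in split_subtexts(raw):
                if classify_context(sub, cues).is_patient_affirmation:
                    found |= match_concepts(sub, th)
    return found


def extract_cohort_concepts(
    notes_by_stay: dict[str, list[dict]],
    th: ConceptThesaurus,
    cues: CueConfig,
) -> dict[str, set[str]]:
    """Stay-level sets for a whole cohort, keyed by stay id."""
    return {
        sid: extract_stay_concepts(notes, th, cues)
        for sid, notes in notes_by_stay.items()
    }


# -- artifact I/O --------------------------------------------------------


def write_mentions_csv(mentions: list[ConceptMention], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["stay_id", "sentence_index", "concept_id", "subject", "polarity", "matched_term"])
        for m in mentions:
            w.writerow(
                [m.stay_id, m.sentence_index, m.concept_id, m.context.subject, m.context.polarity, m.matched_term]
            )


def write_stay_concepts_json(concepts_by_stay: dict[str, set[str]], path: str | Path) -> None:
    payload = {sid: sorted(cids) for sid, cids in sorted(concepts_by_stay.items())}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_stay_concepts_json(path: str | Path) -> dict[str, set[str]]:
    payload = json.loads(Path(path).read_text())
    return {sid: set(cids) for sid, cids in payload.items()}
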