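"""Hierarchical concept thesaurus with synonym terms.

A thesaurus is a rooted forest of concepts (single parent each), the
stand-in for a clinical meta-thesaurus such as the UMLS.  Each concept
carries a preferred term plus synonyms; all terms are normalized
(case-fold, accent-fold, whitespace-collapse) so that "exact match"
against note text is well defined for accented clinical language.

Multi-parent hierarchies are deliberately not supported: every concept
has at most one parent, which keeps ancestor queries unambiguous.  A
licensed vocabulary subset can be dropped in as long as it is exported
to the single-parent TSV format understood by :func:`load_thesaurus`.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Concept",
    "ConceptThesaurus",
    "ThesaurusFormatError",
    "UnknownConceptError",
    "normalize_term",
    "load_thesaurus",
    "save_thesaurus",
]

_WS_RE = re.compile(r"\s+")


class ThesaurusFormatError(ValueError):
    """Raised when a thesaurus file violates the format invariants."""


class UnknownConceptError(KeyError):
    """Raised when a concept id is not present in the thesaurus."""


def normalize_term(term: str) -> str:
    """Normalize a term or free-text fragment for exact matching.

    Case-fold, strip diacritics (NFKD, drop combining marks), and
    collapse internal whitespace.  ``"  Douleur  Abdominale "`` and
    ``"douleur abdominale"`` normalize identically.
    """
    decomposed = unicodedata.normalize("NFKD", term.casefold())
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return _WS_RE.sub(" ", stripped).strip()


@dataclass(frozen=True)
class Concept:
    """One node of the hierarchy.

    ``parent_id`` is ``None`` for a root.  ``synonyms`` holds normalized
    alternative terms; the normalized preferred term is always a valid
    term for the concept as well.
    """

    concept_id: str
    parent_id: str | None
    preferred_term: str
    synonyms: frozenset[str] = field(default_factory=frozenset)

    @property
    def terms(self) -> frozenset[str]:
        """All normalized terms (preferred + synonyms)."""
        return self.synonyms | {normalize_term(self.preferred_term)}


class ConceptThesaurus:
    """Immutable container over concepts with term and ancestor indexes.

    Invariants enforced at construction: unique concept ids, acyclic
    parent chains ending at a root, every parent id known, every
    normalized term mapping to exactly one concept.
    """

    def __init__(self, concepts: list[Concept]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self._concepts:
                raise ThesaurusFormatError(f"duplicate concept id: {c.concept_id!r}")
            self._concepts[c.concept_id] = c

        for c in concepts:
            if c.parent_id is not None and c.parent_id not in self._concepts:
                raise ThesaurusFormatError(
                    f"concept {c.concept_id!r} references unknown parent {c.parent_id!r}"
                )
        self._check_acyclic()

        self._term_index: dict[str, str] = {}
        for c in concepts:
            for term in sorted(c.terms):
                if not term:
                    raise ThesaurusFormatError(
                        f"concept {c.concept_id!r} has an empty term after normalization"
                    )
                owner = self._term_index.get(term)
                if owner is not None and owner != c.concept_id:
                    raise ThesaurusFormatError(
                        f"term {term!r} maps to both {owner!r} and {c.concept_id!r}"
                    )
                self._term_index[term] = c.concept_id

        self._children: dict[str, list[str]] = {cid: [] for cid in self._concepts}
        for c in concepts:
            if c.parent_id is not None:
                self._children[c.parent_id].append(c.concept_id)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done
        for start in self._concepts:
            path = []
            cid: str | None = start
            while cid is not None and cid not in state:
                path.append(cid)
                state[cid] = 0
                cid = self._concepts[cid].parent_id
            if cid is not None and state.get(cid) == 0:
                raise ThesaurusFormatError(f"cycle in parent chain at {cid!r}")
            for p in path:
                state[p] = 1

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __iter__(self):
        return iter(self._concepts.values())

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self._concepts)

    @property
    def term_index(self) -> dict[str, str]:
        """Normalized term -> concept id (copy)."""
        return dict(self._term_index)

    def get(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def children(self, concept_id: str) -> list[str]:
        self.get(concept_id)
        return sorted(self._children[concept_id])

    def is_leaf(self, concept_id: str) -> bool:
        """True iff no concept lists ``concept_id`` as its parent."""
        self.get(concept_id)
        return not self._children[concept_id]

    def ancestors(self, concept_id: str) -> list[str]:
        """Proper ancestors, nearest first."""
        out = []
        cid = self.get(concept_id).parent_id
        while cid is not None:
            out.append(cid)
            cid = self._concepts[cid].parent_id
        return out

    def is_ancestor(self, ancestor_id: str, descendant_id: str) -> bool:
        """True iff ``ancestor_id`` is a *proper* ancestor of ``descendant_id``."""
        self.get(ancestor_id)
        return ancestor_id in self.ancestors(descendant_id)

    def most_precise(self, matched: set[str]) -> set[str]:
        """Reduce a matched set to its most precise members.

        Drops every concept that is a proper ancestor of another member;
        unrelated concepts are all kept.  Idempotent, and the result is
        always a subset of the input.  A matched concept with no matched
        descendant is kept even if it is not a leaf of the tree.
        """
        for cid in matched:
            self.get(cid)
        return {
            cid
            for cid in matched
            if not any(other != cid and self.is_ancestor(cid, other) for other in matched)
        }


def load_thesaurus(path: str | Path) -> ConceptThesaurus:
    """Load a thesaurus from TSV.

    Columns: ``concept_id``, ``parent_id`` (empty for a root),
    ``preferred_term``, ``synonyms`` (pipe-separated, may be empty).
    Raises :class:`ThesaurusFormatError` on cycles, unknown parents or a
    normalized term claimed by two concepts.
    """
    path = Path(path)
    concepts: list[Concept] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["concept_id", "parent_id", "preferred_term", "synonyms"]
        if header != expected:
            raise ThesaurusFormatError(f"bad header {header!r}, expected {expected!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ThesaurusFormatError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            cid, parent, preferred, syns = parts
            concepts.append(
                Concept(
                    concept_id=cid,
                    parent_id=parent or None,
                    preferred_term=preferred,
                    synonyms=frozenset(
                        normalize_term(s) for s in syns.split("|") if s.strip()
                    ),
                )
            )
    return ConceptThesaurus(concepts)


def save_thesaurus(th: ConceptThesaurus, path: str | Path) -> None:
    """Write the TSV representation (lossless for ids, parents, normalized terms)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("concept_id\tparent_id\tpreferred_term\tsynonyms\n")
        for cid in th.concept_ids:
            c = th.get(cid)
            fh.write(
                f"{c.concept_id}\t{c.parent_id or ''}\t{c.preferred_term}\t"
                f"{'|'.join(sorted(c.synonyms))}\n"
            )
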