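"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive the contracts from scratch — exhaustive
term-by-position matching and a restart-on-every-step roll-up — and
must stay independent of the code paths they verify.
"""

import re
import unicodedata


def _norm(s: str) -> str:
    s = unicodedata.normalize("NFKD", s.casefold())
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return " ".join(s.split())


def brute_force_match(sentence: str, th) -> set[str]:
    """Try every thesaurus term at every token position, then resolve.

    Overlaps resolve longest-first (ties: earliest start, then concept
    id) with single-use tokens; the survivors are reduced by an explicit
    pairwise ancestor sweep.
    """
    tokens = re.findall(r"\w+", _norm(sentence))
    candidates = []
    for term, cid in th.term_index.items():
        term_tokens = re.findall(r"\w+", term)
        for start in range(len(tokens) - len(term_tokens) + 1):
            if tokens[start : start + len(term_tokens)] == term_tokens:
                candidates.append((len(term_tokens), start, cid))
    used: set[int] = set()
    chosen: set[str] = set()
    for length, start, cid in sorted(candidates, key=lambda x: (-x[0], x[1], x[2])):
        span = set(range(start, start + length))
        if span & used:
            continue
        used |= span
        chosen.add(cid)

    def ancestors(cid: str) -> set[str]:
        out = set()
        parent = th.get(cid).parent_id
        while parent is not None:
            out.add(parent)
            parent = th.get(parent).parent_id
        return out

    return {c for c in chosen if not any(c in ancestors(o) for o in chosen if o != c)}


def brute_force_rollup(code_counts: dict[str, int]) -> dict[str, str]:
    """Fix-point roll-up by restart-scan: find the single deficient
    surviving code that is longest (ties: lexicographically last), roll
    it up one character, and start over until nothing is deficient."""
    mapping = {c: c for c in code_counts}
    while True:
        pooled: dict[str, int] = {}
        for orig, cur in mapping.items():
            pooled[cur] = pooled.get(cur, 0) + code_counts[orig]
        deficient = sorted(
            (c for c, n in pooled.items() if n < 5 and len(c) > 3),
            key=lambda c: (len(c), c),
        )
        if not deficient:
            return mapping
        victim = deficient[-1]
        mapping = {o: (c[:-1] if c == victim else c) for o, c in mapping.items()}
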