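"""Independent brute-force oracle for the sentence matcher.

Deliberately shares no code with fxtag: branches are expanded to concrete
strings by string rewriting (innermost group first), occurrences are found
by naive substring search with explicit word-edge checks, and the
modifier/site pairing rule is an exhaustive scan over occurrence pairs in
both orders.
"""

from __future__ import annotations

import re

GAP = "\x00"

_GROUP_RE = re.compile(r"\(([^()]*)\)(\?)?")


def expand_all(branch: str) -> set[tuple[str, ...]]:
    """Every concrete expansion of a normalized branch.

    Returns tuples of literal segments; a ``.*`` in the branch becomes a
    segment boundary (the matcher's unbounded within-sentence gap).
    """
    work = [branch.replace(".*", GAP)]
    done: set[str] = set()
    while work:
        s = work.pop()
        m = _GROUP_RE.search(s)
        if m is not None:
            options = m.group(1).split("|")
            if m.group(2):  # optional group
                options = options + [""]
            for opt in set(options):
                work.append(s[: m.start()] + opt + s[m.end() :])
            continue
        q = s.find("?")
        if q > 0:
            # '?' on a single character
            work.append(s[: q - 1] + s[q + 1 :])
            work.append(s[:q] + s[q + 1 :])
            continue
        if q == 0:
            raise ValueError(f"dangling '?' in {branch!r}")
        done.add(s)
    return {tuple(x.split(GAP)) for x in done}


def _is_word(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def bounded_occurrences(
    segments: tuple[str, ...], text: str
) -> set[tuple[int, int]]:
    """All (start, end) spans where the segments occur in order.

    The first segment's start and the last segment's end must fall on word
    edges; inner segment edges are unconstrained (they abut the branch's
    own ``.*`` gap, which carries no boundary assertion).
    """
    spans: set[tuple[int, int]] = set()

    def rec(idx: int, pos: int, start: int) -> None:
        if idx == len(segments):
            if pos == len(text) or not _is_word(text[pos]):
                spans.add((start, pos))
            return
        seg = segments[idx]
        j = text.find(seg, pos)
        while j != -1:
            if idx == 0:
                if j == 0 or not _is_word(text[j - 1]):
                    rec(1, j + len(seg), j)
            else:
                rec(idx + 1, j + len(seg), start)
            j = text.find(seg, j + 1)

    rec(0, 0, -1)
    return spans


def build_expansions(branches: list[str]) -> list[tuple[str, ...]]:
    """Lowercased expansion set for a list of normalized branches."""
    out: set[tuple[str, ...]] = set()
    for branch in branches:
        for exp in expand_all(branch):
            out.add(tuple(seg.lower() for seg in exp))
    return sorted(out)


def all_occurrences(
    expansions: list[tuple[str, ...]], text_lower: str
) -> set[tuple[int, int]]:
    spans: set[tuple[int, int]] = set()
    for exp in expansions:
        spans |= bounded_occurrences(exp, text_lower)
    return spans


def oracle_sentence(
    text: str,
    site_expansions: dict[str, list[tuple[str, ...]]],
    modifier_expansions: list[tuple[str, ...]],
) -> dict[str, str]:
    """Expected {category: order} for one sentence.

    A site fires iff some modifier occurrence and some site occurrence
    exist with one ending at or before the other's start; modifier-first
    wins the tie when both orders are possible.
    """
    t = text.lower()
    mod_spans = all_occurrences(modifier_expansions, t)
    if not mod_spans:
        return {}
    result: dict[str, str] = {}
    for category, expansions in site_expansions.items():
        cat_spans = all_occurrences(expansions, t)
        if not cat_spans:
            continue
        mod_first = any(
            me <= cs for _, me in mod_spans for cs, _ in cat_spans
        )
        cat_first = any(
            ce <= ms for _, ce in cat_spans for ms, _ in mod_spans
        )
        if mod_first:
            result[category] = "modifier_first"
        elif cat_first:
            result[category] = "category_first"
    return result
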