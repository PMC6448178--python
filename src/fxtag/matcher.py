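"""Sentence-level fracture matching and exclusion rules.

A fracture mention is asserted for a site when a fracture modifier and a
site term co-occur within one sentence, in either order, each bounded by
word edges:

    (?<!w)(MODIFIER)(?!w) .*? (?<!w)(SITE)(?!w)      -> "modifier_first"
    (?<!w)(SITE)(?!w) .*? (?<!w)(MODIFIER)(?!w)      -> "category_first"

The gap between the two halves is bounded only by the sentence, so
sentence segmentation is the effective gap control: a run-on sentence lets
a modifier reach across what should have been two statements (a known
failure mode), and a missed split has the same effect.

Exclusion is sentence-scoped: if any exclusion keyword ("rule out", "r/o",
"negative") occurs anywhere in the sentence, every mention in that
sentence is flagged excluded.  Scoped negation ("does not appear ...") and
co-reference across sentences are deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .lexicon import (
    BOUND_LEFT,
    BOUND_RIGHT,
    CATEGORY_IDS,
    ModifierSet,
    PatternSet,
)
from .preprocess import RadiologyReport, Sentence, segment_report

__all__ = [
    "FractureMention",
    "ExclusionConfig",
    "RuleMatcher",
    "match_sentence",
    "apply_exclusion_rules",
    "tag_document",
    "tag_patient",
    "tag_corpus",
    "write_mentions_tsv",
    "DEFAULT_EXCLUSION_KEYWORDS",
]

#: The printed exclusion keyword list, exactly as published.
DEFAULT_EXCLUSION_KEYWORDS: tuple[str, ...] = ("rule out", "r/o", "negative")

LabelVector = dict[str, bool]


@dataclass(frozen=True)
class FractureMention:
    """A single sentence-level hit for one fracture site."""

    category: str
    patient_id: str
    note_id: str
    sentence_index: int
    modifier_span: tuple[int, int]  # half-open, within the sentence
    category_span: tuple[int, int]
    order: str  # "modifier_first" | "category_first"
    excluded: bool = False
    exclusion_keyword: str = ""


@dataclass(frozen=True)
class ExclusionConfig:
    """Exclusion keywords and their scope.

    ``scope`` is ``"sentence"`` (the published behavior: any keyword
    anywhere in the sentence suppresses every mention in it) or
    ``"pre_category"`` (an extension, off by default: only keywords ending
    before the site span suppress a mention).
    """

    keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
    scope: str = "sentence"

    def __post_init__(self) -> None:
        if self.scope not in ("sentence", "pre_category"):
            raise ValueError(f"unknown exclusion scope {self.scope!r}")


def _keyword_regexes(
    keywords: Sequence[str],
) -> list[tuple[str, re.Pattern[str]]]:
    return [
        (kw, re.compile(BOUND_LEFT + re.escape(kw) + BOUND_RIGHT, re.IGNORECASE))
        for kw in keywords
    ]


class RuleMatcher:
    """Compiled bidirectional rules for every site in a pattern set.

    Construction compiles two rule regexes per site (modifier-first and
    site-first).  Reuse one instance across a corpus; construction cost is
    ~40 regex compilations.
    """

    def __init__(
        self,
        patterns: PatternSet,
        modifiers: ModifierSet,
        exclusion: ExclusionConfig | None = None,
    ) -> None:
        self.patterns = patterns
        self.modifiers = modifiers
        self.exclusion = exclusion or ExclusionConfig()
        mod_alt = modifiers.alternation()
        self._rules: dict[str, tuple[re.Pattern[str], re.Pattern[str]]] = {}
        for category in patterns.categories:
            cat_alt = patterns.alternation(category)
            mod_first = re.compile(
                f"{BOUND_LEFT}(?P<mod>{mod_alt}){BOUND_RIGHT}"
                f".*?"
                f"{BOUND_LEFT}(?P<cat>{cat_alt}){BOUND_RIGHT}",
                re.IGNORECASE,
            )
            cat_first = re.compile(
                f"{BOUND_LEFT}(?P<cat>{cat_alt}){BOUND_RIGHT}"
                f".*?"
                f"{BOUND_LEFT}(?P<mod>{mod_alt}){BOUND_RIGHT}",
                re.IGNORECASE,
            )
            self._rules[category] = (mod_first, cat_first)
        self._exclusion_res = _keyword_regexes(self.exclusion.keywords)

    # -- sentence level ------------------------------------------------

    def match_sentence(self, sentence: Sentence) -> list[FractureMention]:
        """All mentions in one sentence, exclusion flags unset.

        At most one mention per site per sentence; when both orders match,
        modifier-first is reported (fixed tie-break).  Spans are the
        first-found pair, leftmost with the shortest gap.
        """
        mentions: list[FractureMention] = []
        text = sentence.text
        for category, (mod_first, cat_first) in self._rules.items():
            m = mod_first.search(text)
            if m is not None:
                mentions.append(
                    FractureMention(
                        category=category,
                        patient_id=sentence.patient_id,
                        note_id=sentence.note_id,
                        sentence_index=sentence.index,
                        modifier_span=m.span("mod"),
                        category_span=m.span("cat"),
                        order="modifier_first",
                    )
                )
                continue
            m = cat_first.search(text)
            if m is not None:
                mentions.append(
                    FractureMention(
                        category=category,
                        patient_id=sentence.patient_id,
                        note_id=sentence.note_id,
                        sentence_index=sentence.index,
                        modifier_span=m.span("mod"),
                        category_span=m.span("cat"),
                        order="category_first",
                    )
                )
        return mentions

    def apply_exclusion_rules(
        self, mentions: Iterable[FractureMention], sentence: Sentence
    ) -> list[FractureMention]:
        """Set the excluded flag on mentions of one sentence.

        With sentence scope, the first keyword (in config order) found
        anywhere in the sentence excludes every mention; with
        pre_category scope a mention is excluded only when some keyword
        occurrence ends at or before its site span start.
        """
        out: list[FractureMention] = []
        if self.exclusion.scope == "sentence":
            hit = ""
            for kw, rx in self._exclusion_res:
                if rx.search(sentence.text):
                    hit = kw
                    break
            for m in mentions:
                out.append(
                    replace(m, excluded=bool(hit), exclusion_keyword=hit)
                    if hit
                    else m
                )
            return out
        for m in mentions:
            hit = ""
            for kw, rx in self._exclusion_res:
                if any(
                    km.end() <= m.category_span[0]
                    for km in rx.finditer(sentence.text)
                ):
                    hit = kw
                    break
            out.append(
                replace(m, excluded=True, exclusion_keyword=hit) if hit else m
            )
        return out

    # -- document / patient level --------------------------------------

    def tag_document(
        self, report: RadiologyReport
    ) -> tuple[LabelVector, list[FractureMention]]:
        """Label one note; returns the label vector and all mentions.

        A site is labeled true iff some non-excluded mention for it exists
        in any sentence; excluded mentions are still returned for audit.
        """
        labels: LabelVector = {c: False for c in self.patterns.categories}
        mentions: list[FractureMention] = []
        for sentence in segment_report(report):
            found = self.apply_exclusion_rules(
                self.match_sentence(sentence), sentence
            )
            for m in found:
                if not m.excluded:
                    labels[m.category] = True
            mentions.extend(found)
        return labels, mentions

    def tag_patient(
        self, reports: Sequence[RadiologyReport]
    ) -> tuple[LabelVector, list[FractureMention]]:
        """Element-wise OR of document labels for one patient's notes."""
        patient_ids = {r.patient_id for r in reports}
        if len(patient_ids) > 1:
            raise ValueError(
                "tag_patient received notes from multiple patients: "
                + ", ".join(sorted(patient_ids))
            )
        labels: LabelVector = {c: False for c in self.patterns.categories}
        mentions: list[FractureMention] = []
        for report in reports:
            doc_labels, doc_mentions = self.tag_document(report)
            for c, v in doc_labels.items():
                labels[c] = labels[c] or v
            mentions.extend(doc_mentions)
        return labels, mentions

    def tag_corpus(
        self, reports: Sequence[RadiologyReport]
    ) -> tuple[dict[str, LabelVector], list[FractureMention]]:
        """Patient-level labels for a whole corpus, keyed by patient id."""
        by_patient: dict[str, list[RadiologyReport]] = {}
        for r in reports:
            by_patient.setdefault(r.patient_id, []).append(r)
        labels: dict[str, LabelVector] = {}
        mentions: list[FractureMention] = []
        for pid in sorted(by_patient):
            plabels, pmentions = self.tag_patient(by_patient[pid])
            labels[pid] = plabels
            mentions.extend(pmentions)
        return labels, mentions


# -- functional wrappers (cache the compiled rules on the pattern set) ----


def _cached_matcher(
    patterns: PatternSet,
    modifiers: ModifierSet,
    exclusion: ExclusionConfig | None = None,
) -> RuleMatcher:
    cache = getattr(patterns, "_matcher_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(patterns, "_matcher_cache", cache)
    key = (id(modifiers), exclusion or ExclusionConfig())
    if key not in cache:
        cache[key] = RuleMatcher(patterns, modifiers, exclusion)
    return cache[key]


def match_sentence(
    sentence: Sentence, patterns: PatternSet, modifiers: ModifierSet
) -> list[FractureMention]:
    """See :meth:`RuleMatcher.match_sentence`."""
    return _cached_matcher(patterns, modifiers).match_sentence(sentence)


def apply_exclusion_rules(
    mentions: Iterable[FractureMention],
    sentence: Sentence,
    config: ExclusionConfig | None = None,
) -> list[FractureMention]:
    """Standalone exclusion pass (no pattern sets needed)."""
    config = config or ExclusionConfig()
    out: list[FractureMention] = []
    if config.scope == "sentence":
        hit = ""
        for kw, rx in _keyword_regexes(config.keywords):
            if rx.search(sentence.text):
                hit = kw
                break
        for m in mentions:
            out.append(
                replace(m, excluded=True, exclusion_keyword=hit) if hit else m
            )
        return out
    for m in mentions:
        hit = ""
        for kw, rx in _keyword_regexes(config.keywords):
            if any(
                km.end() <= m.category_span[0]
                for km in rx.finditer(sentence.text)
            ):
                hit = kw
                break
        out.append(
            replace(m, excluded=True, exclusion_keyword=hit) if hit else m
        )
    return out


def tag_document(
    report: RadiologyReport,
    patterns: PatternSet,
    modifiers: ModifierSet,
    exclusion: ExclusionConfig | None = None,
) -> tuple[LabelVector, list[FractureMention]]:
    """See :meth:`RuleMatcher.tag_document`."""
    return _cached_matcher(patterns, modifiers, exclusion).tag_document(report)


def tag_patient(
    reports: Sequence[RadiologyReport],
    patterns: PatternSet,
    modifiers: ModifierSet,
    exclusion: ExclusionConfig | None = None,
) -> tuple[LabelVector, list[FractureMention]]:
    """See :meth:`RuleMatcher.tag_patient`."""
    return _cached_matcher(patterns, modifiers, exclusion).tag_patient(reports)


def tag_corpus(
    reports: Sequence[RadiologyReport],
    patterns: PatternSet,
    modifiers: ModifierSet,
    exclusion: ExclusionConfig | None = None,
) -> tuple[dict[str, LabelVector], list[FractureMention]]:
    """See :meth:`RuleMatcher.tag_corpus`."""
    return _cached_matcher(patterns, modifiers, exclusion).tag_corpus(reports)


def write_mentions_tsv(mentions: Iterable[FractureMention], path) -> None:
    """Audit dump of all mentions, including excluded ones."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "patient_id\tnote_id\tsentence_index\tcategory\t"
            "modifier_start\tmodifier_end\tcategory_start\tcategory_end\t"
            "order\texcluded\texclusion_keyword\n"
        )
        for m in mentions:
            fh.write(
                f"{m.patient_id}\t{m.note_id}\t{m.sentence_index}\t"
                f"{m.category}\t{m.modifier_span[0]}\t{m.modifier_span[1]}\t"
                f"{m.category_span[0]}\t{m.category_span[1]}\t{m.order}\t"
                f"{int(m.excluded)}\t{m.exclusion_keyword}\n"
            )
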