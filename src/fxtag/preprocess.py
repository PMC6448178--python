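"""Report corpora and sentence segmentation.

Reports arrive as JSON Lines, one object per radiology note with keys
``patient_id``, ``note_id``, ``note_type`` and ``text``.  The unit of rule
application downstream is the sentence, so each note is segmented here.

The segmenter is deliberately simple and fully specified: it splits after
sentence-final ``. ``, ``? `` or ``! `` and at any newline run (radiology
notes are line-oriented), and suppresses the period split after a small
configurable abbreviation list ("Dr.", "vs.", ...) or a single capital
initial ("J.").  Offsets are 0-based half-open into the original note text,
which is never lowercased or otherwise altered, so every sentence satisfies
``text == note_text[start:end]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "RadiologyReport",
    "Sentence",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "segment_sentences",
    "segment_report",
    "default_abbreviations",
    "write_sentences_tsv",
]

PathLike = Union[str, Path]

_REQUIRED_KEYS = ("patient_id", "note_id", "note_type", "text")
_TERMINATORS = ".?!"


class CorpusError(ValueError):
    """Raised for malformed corpus files."""


@dataclass(frozen=True)
class RadiologyReport:
    """One free-text radiology note."""

    patient_id: str
    note_id: str
    note_type: str
    text: str


@dataclass(frozen=True)
class Sentence:
    """One segmented sentence; offsets index into the original note text."""

    patient_id: str
    note_id: str
    index: int
    start: int
    end: int
    text: str


def read_corpus(path: PathLike) -> list[RadiologyReport]:
    """Read a JSON Lines corpus, preserving file order.

    Empty-text records are retained (they yield zero sentences downstream).
    Malformed lines and duplicate ``(patient_id, note_id)`` pairs are
    errors naming the offending line.
    """
    reports: list[RadiologyReport] = []
    seen: set[tuple[str, str]] = set()
    try:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise CorpusError(f"cannot read corpus {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
        if not isinstance(record, dict):
            raise CorpusError(f"{path}:{lineno}: expected a JSON object")
        missing = [k for k in _REQUIRED_KEYS if k not in record]
        if missing:
            raise CorpusError(
                f"{path}:{lineno}: missing key(s) {', '.join(missing)}"
            )
        key = (str(record["patient_id"]), str(record["note_id"]))
        if key in seen:
            raise CorpusError(
                f"{path}:{lineno}: duplicate (patient_id, note_id) {key}"
            )
        seen.add(key)
        reports.append(
            RadiologyReport(
                patient_id=key[0],
                note_id=key[1],
                note_type=str(record["note_type"]),
                text=str(record["text"]),
            )
        )
    return reports


def write_corpus(reports: Iterable[RadiologyReport], path: PathLike) -> None:
    """Write reports as JSON Lines (byte-deterministic for fixed input)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "patient_id": r.patient_id,
                        "note_id": r.note_id,
                        "note_type": r.note_type,
                        "text": r.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def default_abbreviations() -> frozenset[str]:
    """The builtin abbreviation guard list (lowercase, period included)."""
    text = (
        resources.files("fxtag.data")
        .joinpath("abbreviations.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(
        ln.strip().lower()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    )


def load_abbreviations(path: PathLike) -> frozenset[str]:
    """Load a user abbreviation guard list (one token per line)."""
    return frozenset(
        ln.strip().lower()
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    )


def _is_guarded_abbreviation(
    text: str, period_pos: int, abbreviations: frozenset[str]
) -> bool:
    """True if the token ending at text[period_pos] suppresses the split."""
    k = period_pos
    while k > 0 and not text[k - 1].isspace():
        k -= 1
    token = text[k : period_pos + 1]
    if token.lower() in abbreviations:
        return True
    # Single capital initial, e.g. "J." in "J. Smith".
    return len(token) == 2 and token[0].isalpha() and token[0].isupper()


def segment_sentences(
    text: str,
    *,
    patient_id: str = "",
    note_id: str = "",
    abbreviations: frozenset[str] | None = None,
) -> list[Sentence]:
    """Segment *text* into ordered, non-overlapping sentences.

    Splits after ``.``, ``?`` or ``!`` followed by a space or tab (unless
    guarded by the abbreviation list) and at every newline run.  Leading
    and trailing whitespace of each sentence is excluded from its span, so
    spans cover exactly the non-delimiter text.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    breaks: list[int] = []  # positions where a new chunk starts
    n = len(text)
    i = 0
    while i < n:
        ch = text[i]
        if ch in "\r\n":
            j = i
            while j < n and text[j] in "\r\n":
                j += 1
            breaks.append(j)
            i = j
            continue
        if ch in _TERMINATORS and i + 1 < n and text[i + 1] in " \t":
            if ch == "." and _is_guarded_abbreviation(text, i, abbreviations):
                i += 1
                continue
            breaks.append(i + 1)
            i += 1
            continue
        i += 1

    sentences: list[Sentence] = []
    starts = [0] + breaks
    ends = breaks + [n]
    index = 0
    for chunk_start, chunk_end in zip(starts, ends):
        s, e = chunk_start, chunk_end
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s == e:
            continue
        sentences.append(
            Sentence(
                patient_id=patient_id,
                note_id=note_id,
                index=index,
                start=s,
                end=e,
                text=text[s:e],
            )
        )
        index += 1
    return sentences


def segment_report(
    report: RadiologyReport,
    abbreviations: frozenset[str] | None = None,
) -> list[Sentence]:
    """Segment a report's text, carrying its identifiers."""
    return segment_sentences(
        report.text,
        patient_id=report.patient_id,
        note_id=report.note_id,
        abbreviations=abbreviations,
    )


def write_sentences_tsv(
    sentences: Iterable[Sentence], path: PathLike
) -> None:
    """Debug dump: patient_id, note_id, index, start, end, text."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id\tnote_id\tindex\tstart\tend\ttext\n")
        for s in sentences:
            safe = s.text.replace("\t", " ").replace("\n", " ")
            fh.write(
                f"{s.patient_id}\t{s.note_id}\t{s.index}\t{s.start}\t"
                f"{s.end}\t{safe}\n"
            )
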