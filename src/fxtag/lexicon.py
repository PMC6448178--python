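"""Fracture-site and fracture-modifier lexicons.

The tagger's knowledge lives in two pattern tables: one regular-expression
alternation per skeletal site (twenty sites, from ankle to vertebral body)
and a single alternation of fracture modifiers ("fracture", "fx", "broken",
...).  A site fires only when a site term and a modifier co-occur in one
sentence, so the two tables are loaded and compiled separately.

The printed source tables contain typesetting artifacts -- trailing spaces
before ``|``, doubled ``||`` (an empty alternation branch would match every
sentence), trailing ``|``, and curly apostrophes.  :func:`normalize_pattern`
repairs exactly those artifacts; the verbatim source text of every row is
retained on the :class:`RawPattern` for audit.

Matching is case-insensitive throughout, and every compiled alternation is
bounded on both sides by word-edge assertions (``(?<!\\w) ... (?!\\w)``),
so "maxillofacial" does not contain a bounded "maxilla" and "colles'" is
still bounded when followed by a period.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "CATEGORIES",
    "CATEGORY_IDS",
    "LexiconError",
    "RawPattern",
    "PatternSet",
    "ModifierSet",
    "Diagnostic",
    "normalize_pattern",
    "load_category_patterns",
    "load_modifier_patterns",
    "lint_lexicon",
    "bounded_regex",
]

#: Word-edge assertions used to bound every alternation.  Lookarounds rather
#: than \b so that branches ending in non-word characters (apostrophes,
#: digits followed by punctuation) are bounded sensibly.
BOUND_LEFT = r"(?<!\w)"
BOUND_RIGHT = r"(?!\w)"

#: The twenty skeletal sites, in report (alphabetical) order:
#: (stable id, display name).
CATEGORIES: tuple[tuple[str, str], ...] = (
    ("ankle", "Ankle"),
    ("clavicle", "Clavicle"),
    ("distal_forearm", "Distal Forearm"),
    ("face", "Face"),
    ("feet_and_toes", "Feet and Toes"),
    ("hand_and_fingers", "Hand and Fingers"),
    ("other_spine", "Other Spine Fractures"),
    ("patella", "Patella"),
    ("pelvis", "Pelvis"),
    ("proximal_femur", "Proximal Femur"),
    ("proximal_humerus", "Proximal Humerus"),
    ("ribs", "Ribs"),
    ("scapula", "Scapula"),
    ("shaft_and_distal_femur", "Shaft and Distal Femur"),
    ("shaft_and_distal_humerus", "Shaft and Distal Humerus"),
    ("shaft_and_proximal_radius_ulna", "Shaft and Proximal Radius/Ulna"),
    ("skull", "Skull"),
    ("sternum", "Sternum"),
    ("tibia_and_fibula", "Tibia and Fibula"),
    ("vertebral_body", "Vertebral Body"),
)

CATEGORY_IDS: tuple[str, ...] = tuple(cid for cid, _ in CATEGORIES)
DISPLAY_NAMES: dict[str, str] = dict(CATEGORIES)

PathLike = Union[str, Path]


class LexiconError(ValueError):
    """Raised for unreadable, empty, or non-compiling lexicon sources."""


@dataclass(frozen=True)
class RawPattern:
    """One verbatim lexicon row, preserved byte-for-byte for audit."""

    category: str
    source_text: str
    provenance: str  # "table2" | "table3" | "user"


def _split_top_level(pattern: str, sep: str = "|") -> list[str]:
    """Split on *sep* at parenthesis depth zero only."""
    parts: list[str] = []
    depth = 0
    buf: list[str] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "\\" and i + 1 < len(pattern):
            buf.append(pattern[i : i + 2])
            i += 2
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
        i += 1
    parts.append("".join(buf))
    return parts


def normalize_pattern(source_text: str) -> str:
    """Normalize one raw pattern row into a clean alternation.

    Splits on top-level ``|``, trims each branch, drops empty branches
    (artifacts of ``||``, trailing ``|`` and spaces before ``|`` in the
    printed tables), folds curly apostrophes to ASCII, and rejoins.
    Inner groups and their contents are untouched.  Idempotent.

    Raises :class:`LexiconError` if every branch is empty after trimming.
    """
    if not source_text:
        raise LexiconError("empty pattern string")
    text = source_text.replace("’", "'").replace("‘", "'")
    branches = [b.strip() for b in _split_top_level(text)]
    branches = [b for b in branches if b]
    if not branches:
        raise LexiconError(
            f"all alternation branches empty after trimming: {source_text!r}"
        )
    return "|".join(branches)


def bounded_regex(alternation: str) -> re.Pattern[str]:
    """Compile *alternation* bounded by word edges, case-insensitive."""
    return re.compile(
        f"{BOUND_LEFT}(?:{alternation}){BOUND_RIGHT}", re.IGNORECASE
    )


def _compile_branches(
    category: str, source_text: str, normalized: str
) -> re.Pattern[str]:
    try:
        return bounded_regex(normalized)
    except re.error as exc:
        raise LexiconError(
            f"pattern for category {category!r} failed to compile: "
            f"{source_text!r} ({exc})"
        ) from exc


@dataclass
class PatternSet:
    """Compiled per-site alternations (the site half of the rule)."""

    raw: dict[str, list[RawPattern]] = field(default_factory=dict)
    branches: dict[str, list[str]] = field(default_factory=dict)
    compiled: dict[str, re.Pattern[str]] = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        return list(self.branches)

    def alternation(self, category: str) -> str:
        """The full normalized alternation string for *category*."""
        return "|".join(self.branches[category])


@dataclass
class ModifierSet:
    """Compiled fracture-modifier alternation (the modifier half)."""

    raw: list[RawPattern] = field(default_factory=list)
    branches: list[str] = field(default_factory=list)
    compiled: re.Pattern[str] | None = None

    def alternation(self) -> str:
        return "|".join(self.branches)


def _read_tsv_rows(path: PathLike) -> list[tuple[str, str]]:
    try:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise LexiconError(f"cannot read lexicon file {path}: {exc}") from exc
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" not in line:
            raise LexiconError(
                f"{path}:{lineno}: expected 'category<TAB>pattern', got {line!r}"
            )
        category, pattern = line.split("\t", 1)
        rows.append((category.strip(), pattern))
    return rows


def _default_sites_rows() -> list[tuple[str, str]]:
    text = (
        resources.files("fxtag.data")
        .joinpath("fracture_sites.tsv")
        .read_text(encoding="utf-8")
    )
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        category, pattern = line.split("\t", 1)
        rows.append((category, pattern))
    return rows


def load_category_patterns(source: PathLike = "default") -> PatternSet:
    """Load and compile the per-site pattern table.

    *source* is ``"default"`` for the builtin twenty-site table, or a path
    to a UTF-8 tab-separated file of ``category<TAB>pattern`` rows (several
    rows per category are allowed; each contributes its branches).
    """
    if source == "default":
        rows = _default_sites_rows()
        provenance = "table2"
    else:
        rows = _read_tsv_rows(source)
        provenance = "user"
    if not rows:
        raise LexiconError(f"no patterns loaded from {source!r}")

    ps = PatternSet()
    for category, pattern in rows:
        if category not in DISPLAY_NAMES:
            raise LexiconError(
                f"unknown category id {category!r} (known: "
                f"{', '.join(CATEGORY_IDS)})"
            )
        normalized = normalize_pattern(pattern)
        _compile_branches(category, pattern, normalized)
        ps.raw.setdefault(category, []).append(
            RawPattern(category, pattern, provenance)
        )
        ps.branches.setdefault(category, []).extend(
            _split_top_level(normalized)
        )
    for category in ps.branches:
        ps.compiled[category] = _compile_branches(
            category, "|".join(r.source_text for r in ps.raw[category]),
            ps.alternation(category),
        )
    return ps


def load_modifier_patterns(source: PathLike = "default") -> ModifierSet:
    """Load and compile the fracture-modifier alternation.

    The builtin default is the single printed modifier row; a user file
    holds one raw pattern per line (no category column).
    """
    if source == "default":
        lines = [
            resources.files("fxtag.data")
            .joinpath("fracture_modifiers.txt")
            .read_text(encoding="utf-8")
            .rstrip("\n")
        ]
        provenance = "table3"
    else:
        try:
            lines = [
                ln
                for ln in Path(source).read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.lstrip().startswith("#")
            ]
        except OSError as exc:
            raise LexiconError(
                f"cannot read modifier file {source}: {exc}"
            ) from exc
        provenance = "user"
    if not lines:
        raise LexiconError(f"no patterns loaded from {source!r}")

    ms = ModifierSet()
    for line in lines:
        normalized = normalize_pattern(line)
        ms.raw.append(RawPattern("modifier", line, provenance))
        ms.branches.extend(_split_top_level(normalized))
    try:
        ms.compiled = bounded_regex(ms.alternation())
    except re.error as exc:
        raise LexiconError(
            f"modifier pattern failed to compile: {lines!r} ({exc})"
        ) from exc
    return ms


@dataclass(frozen=True)
class Diagnostic:
    """A lint warning about the lexicon; never fatal."""

    kind: str  # "collision" | "short_branch" | "bare_dot"
    categories: tuple[str, ...]
    branch: str
    message: str


def _bare_dots(branch: str) -> bool:
    """True if *branch* contains an unescaped '.' that is not a '.*' gap."""
    i = 0
    in_class = False
    while i < len(branch):
        ch = branch[i]
        if ch == "\\":
            i += 2
            continue
        if ch == "[":
            in_class = True
        elif ch == "]":
            in_class = False
        elif ch == "." and not in_class:
            if i + 1 >= len(branch) or branch[i + 1] != "*":
                return True
            i += 2
            continue
        i += 1
    return False


def lint_lexicon(
    patterns: PatternSet, modifiers: ModifierSet | None = None
) -> list[Diagnostic]:
    """Report suspicious lexicon entries (warnings only).

    Flags branches shared verbatim by two or more sites (cross-category
    collisions, e.g. "navicular" under both Feet and Toes and Hand and
    Fingers), branches shorter than three characters (e.g. "mc"), and
    branches containing a bare unescaped "." outside a character class.
    """
    diagnostics: list[Diagnostic] = []
    owners: dict[str, list[str]] = {}
    for category, branches in patterns.branches.items():
        for branch in branches:
            owners.setdefault(branch.casefold(), []).append(category)
    for branch, cats in sorted(owners.items()):
        uniq = sorted(set(cats))
        if len(uniq) >= 2:
            diagnostics.append(
                Diagnostic(
                    "collision",
                    tuple(uniq),
                    branch,
                    f"branch {branch!r} is shared by categories: "
                    f"{', '.join(uniq)}",
                )
            )

    all_branches: list[tuple[str, str]] = [
        (category, branch)
        for category, branches in patterns.branches.items()
        for branch in branches
    ]
    if modifiers is not None:
        all_branches += [("modifier", b) for b in modifiers.branches]
    for category, branch in all_branches:
        if len(branch) < 3:
            diagnostics.append(
                Diagnostic(
                    "short_branch",
                    (category,),
                    branch,
                    f"branch {branch!r} in {category} is shorter than 3 "
                    "characters and may over-match",
                )
            )
        if _bare_dots(branch):
            diagnostics.append(
                Diagnostic(
                    "bare_dot",
                    (category,),
                    branch,
                    f"branch {branch!r} in {category} contains a bare '.' "
                    "outside a character class",
                )
            )
    return diagnostics
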