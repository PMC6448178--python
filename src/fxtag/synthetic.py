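"""Synthetic radiology-style corpora with known gold labels.

The generator emulates the phenomena that make fracture tagging hard in
real reports: affirmative mention sentences built from concrete expansions
of the default lexicon ("Mildly displaced fracture of the left clavicle."),
negated sentences wrapped with an exclusion keyword ("Cannot rule out
..."), distractor sentences naming anatomy with no fracture modifier, and
run-on corruption that joins two statements without a delimiter.  Gold
labels are defined by construction: a patient is positive for a site iff
at least one affirmative, non-negated sentence for that site was planted
in their notes.

The planting vocabulary is restricted to site terms that fire exactly
their own site (cross-category collision terms such as "navicular" or
"supracondylar" are excluded by default), so a corpus generated with no
negation and no run-ons round-trips through the tagger exactly.  A flag
re-enables collision terms to exercise multi-label behavior, and a
``hard_cases`` flag plants co-reference and scoped-negation sentences that
the sentence-scoped rules are expected to get wrong.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

from .lexicon import CATEGORY_IDS
from .preprocess import RadiologyReport

__all__ = [
    "CorpusSpec",
    "SyntheticCorpus",
    "PlantRecord",
    "UnsupportedPatternError",
    "generate_corpus",
    "expand_branch",
    "enumerate_expansions",
    "SAFE_TERMS",
    "COLLISION_TERMS",
]


# ---------------------------------------------------------------------------
# Branch expansion: resolve a normalized lexicon branch to concrete strings.
# ---------------------------------------------------------------------------


class UnsupportedPatternError(ValueError):
    """Raised when a branch uses a construct outside the lexicon dialect."""


_GAP = object()  # sentinel AST node for ".*"


def _parse_alt(branch: str, i: int) -> tuple[tuple, int]:
    options: list[tuple] = []
    current: list[tuple] = []
    n = len(branch)
    while i < n and branch[i] != ")":
        ch = branch[i]
        if ch == "|":
            options.append(("seq", tuple(current)))
            current = []
            i += 1
            continue
        if ch == "(":
            node, i = _parse_group(branch, i)
        elif ch == ".":
            if i + 1 < n and branch[i + 1] == "*":
                node = ("gap",)
                i += 2
            else:
                raise UnsupportedPatternError(
                    f"bare '.' in branch {branch!r} at position {i}"
                )
        elif ch in "*+[]{}^$\\":
            raise UnsupportedPatternError(
                f"unsupported construct {ch!r} in branch {branch!r}"
            )
        else:
            node = ("lit", ch)
            i += 1
        if i < n and branch[i] == "?":
            node = ("opt", node)
            i += 1
        current.append(node)
    options.append(("seq", tuple(current)))
    if len(options) > 1:
        return ("alt", tuple(options)), i
    return options[0], i


def _parse_group(branch: str, i: int) -> tuple[tuple, int]:
    node, j = _parse_alt(branch, i + 1)
    if j >= len(branch) or branch[j] != ")":
        raise UnsupportedPatternError(f"unbalanced '(' in branch {branch!r}")
    return node, j + 1


def _parse_branch(branch: str) -> tuple:
    node, i = _parse_alt(branch, 0)
    if i != len(branch):
        raise UnsupportedPatternError(f"unbalanced ')' in branch {branch!r}")
    return node


def _concat(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
    return a[:-1] + (a[-1] + b[0],) + b[1:]


def _expand_node(node: tuple, cap: int) -> list[tuple[str, ...]]:
    kind = node[0]
    if kind == "lit":
        return [(node[1],)]
    if kind == "gap":
        return [("", "")]  # a segment boundary
    if kind == "opt":
        opts = _expand_node(node[1], cap) + [("",)]
        return list(dict.fromkeys(opts))
    if kind == "alt":
        out: list[tuple[str, ...]] = []
        for option in node[1]:
            out.extend(_expand_node(option, cap))
        return list(dict.fromkeys(out))
    if kind == "seq":
        result: list[tuple[str, ...]] = [("",)]
        for item in node[1]:
            opts = _expand_node(item, cap)
            result = [_concat(a, b) for a in result for b in opts]
            if len(result) > cap:
                raise UnsupportedPatternError(
                    f"branch expands to more than {cap} alternatives"
                )
        return list(dict.fromkeys(result))
    raise AssertionError(kind)


def enumerate_expansions(
    branch: str, cap: int = 10_000
) -> list[tuple[str, ...]]:
    """All concrete expansions of a normalized branch.

    Each expansion is a tuple of literal segments; a ``.*`` gap in the
    branch separates segments.  Branches without gaps yield 1-tuples.
    """
    return _expand_node(_parse_branch(branch), cap)


def expand_branch(
    branch: str, seed: int | random.Random | None = None
) -> str:
    """One concrete expansion of a normalized branch, gaps drawn as " ".

    The result matches its source branch under the matcher's compiled
    (case-insensitive) pattern.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    expansions = enumerate_expansions(branch)
    segments = rng.choice(expansions)
    return " ".join(segments) if len(segments) > 1 else segments[0]


# ---------------------------------------------------------------------------
# Planting vocabulary.
# ---------------------------------------------------------------------------

#: Site terms that fire exactly their own site when planted sentence-final
#: after a modifier.  Every term is a concrete expansion of a default-lexicon
#: branch with word-character edges; terms shared across sites or swallowed
#: by another site's patterns (e.g. "navicular", "cervical", " head") are
#: kept out (see COLLISION_TERMS).
SAFE_TERMS: dict[str, tuple[str, ...]] = {
    "ankle": ("ankle", "trimalleolar", "bimalleolar", "tillaux"),
    "clavicle": ("clavicle", "clavical", "collar bone", "clav"),
    "distal_forearm": ("wrist", "styloid process", "smith's"),
    "face": ("nasal", "mandible", "zygomatic", "palate", "malar bone"),
    "feet_and_toes": ("metatarsal", "calcaneus", "cuboid", "talus", "heel", "toe"),
    "hand_and_fingers": (
        "scaphoid", "lunate", "thumb", "capitate", "hamate", "metacarpal",
        "finger",
    ),
    "other_spine": (
        "coccyx", "pedicle", "spinous process", "neural arch",
        "transverse process",
    ),
    "patella": ("patella", "patellar", "kneecap"),
    "pelvis": ("acetabulum", "pubis", "sacrum", "ilium", "ischium"),
    "proximal_femur": (
        "intertrochanteric", "pertrochanteric", "intracapsular",
        "greater trochanter",
    ),
    "proximal_humerus": ("proximal humerus", "extracapsular", "head of humerus"),
    "ribs": ("rib", "ribs", "rib cage"),
    "scapula": ("scapula", "acromion", "glenoid", "shoulder blade", "coracoid"),
    "shaft_and_distal_femur": ("subtrochanteric", "mid femur", "shaft of femur"),
    "shaft_and_distal_humerus": ("elbow", "epicondyle", "shaft of humerus"),
    "shaft_and_proximal_radius_ulna": (
        "olecranon", "monteggia", "galeazzi", "ulnar shaft",
    ),
    "skull": ("occipital", "calvarium", "calvarial", "sphenoid"),
    "sternum": ("sternum", "manubrium", "xyphoid", "breastbone"),
    "tibia_and_fibula": ("fibula", "tibial shaft", "lateral tibial plateau"),
    "vertebral_body": ("endplate", "biconcave", "lumbar", "L2", "T11"),
}

#: Terms that legitimately fire more than one site under the printed
#: patterns; planted only when collision terms are enabled, to test
#: multi-label behavior.
COLLISION_TERMS: dict[str, tuple[str, ...]] = {
    "feet_and_toes": ("navicular",),
    "hand_and_fingers": ("navicular",),
    "shaft_and_distal_femur": ("supracondylar",),
    "shaft_and_distal_humerus": ("supracondylar",),
    "other_spine": ("cervical vertebrae",),
    "vertebral_body": ("t-spine",),
}

_MODIFIER_WORDS = (
    "fracture", "fractures", "fractured", "microfracture", "fx", "fxs",
    "broken", "cracked", "displaced", "fragment", "separation",
)

# Site terms are always sentence-final so that patterns requiring a
# trailing space (e.g. "humerus ") cannot leak across template words.
_AFFIRMATIVE_TEMPLATES = (
    "{mod} of the {term}.",
    "{mod} of the left {term}.",
    "{mod} involving the right {term}.",
    "Comminuted {mod} of the {term}.",
    "Acute {mod} seen at the {term}.",
)

_NEGATED_TEMPLATES = (
    "Cannot rule out {mod} of the {term}.",
    "Negative for {mod} of the {term}.",
    "R/o {mod} of the {term}.",
)

_DISTRACTOR_TEMPLATES = (
    "Normal alignment of the {term}.",
    "Intact appearance of the {term}.",
    "Degenerative change about the {term}.",
)

_NEUTRAL_SENTENCES = (
    "Radiographic views obtained.",
    "Comparison made with prior study.",
    "Soft tissues are unremarkable.",
)

_NOTE_TYPES = ("X-ray", "CT", "MRI")

# Hard cases: sentences the sentence-scoped printed rules are expected to
# get wrong (cross-sentence co-reference; scoped negation phrasing outside
# the printed keyword list).
_COREF_TEMPLATES = (
    "Cortical irregularity of the {term}. Findings likely represent a small "
    "fracture.",
)
_SCOPED_NEGATION_TEMPLATES = (
    "It does not appear the {term} fracture is the cause of pain.",
)


# ---------------------------------------------------------------------------
# Corpus specification and generation.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    ``prevalence`` is the per-site probability that a patient truly has a
    fracture there (a scalar applies to every site); ``negation_rate`` is
    the probability that a planted mention sentence is wrapped with an
    exclusion keyword (making it not count toward gold); ``distractor_rate``
    governs anatomy-only sentences per note; ``runon_rate`` joins adjacent
    sentences without a delimiter.
    """

    n_patients: int = 100
    prevalence: Union[float, Mapping[str, float]] = 0.08
    notes_per_patient: tuple[int, int] = (1, 3)
    negation_rate: float = 0.1
    distractor_rate: float = 0.3
    runon_rate: float = 0.05
    seed: int = 0
    hard_case_rate: float = 0.0
    allow_collision_terms: bool = False

    def prevalence_for(self, category: str) -> float:
        if isinstance(self.prevalence, Mapping):
            return float(self.prevalence.get(category, 0.0))
        return float(self.prevalence)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("notes_per_patient must satisfy 1 <= lo <= hi")
        rates = {
            "negation_rate": self.negation_rate,
            "distractor_rate": self.distractor_rate,
            "runon_rate": self.runon_rate,
            "hard_case_rate": self.hard_case_rate,
        }
        for category in CATEGORY_IDS:
            rates[f"prevalence[{category}]"] = self.prevalence_for(category)
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PlantRecord:
    """Provenance for one planted sentence (or merged run-on pair)."""

    patient_id: str
    note_id: str
    kind: str  # affirmative | negated | distractor | neutral | runon |
    #           hard_coref | hard_scoped_negation
    category: str | None
    text: str


@dataclass
class SyntheticCorpus:
    """Generated reports, gold patient labels, and planting provenance."""

    reports: list[RadiologyReport]
    gold: dict[str, dict[str, bool]]
    provenance: list[PlantRecord]
    spec: CorpusSpec


def _planting_vocabulary(spec: CorpusSpec) -> dict[str, tuple[str, ...]]:
    vocab = {c: SAFE_TERMS[c] for c in CATEGORY_IDS}
    if spec.allow_collision_terms:
        vocab = {
            c: vocab[c] + COLLISION_TERMS.get(c, ())
            for c in CATEGORY_IDS
        }
    return vocab


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate one corpus; the same spec yields a byte-identical corpus."""
    spec.validate()
    rng = random.Random(spec.seed)
    vocab = _planting_vocabulary(spec)

    reports: list[RadiologyReport] = []
    gold: dict[str, dict[str, bool]] = {}
    provenance: list[PlantRecord] = []

    for p in range(spec.n_patients):
        pid = f"p{p:04d}"
        gold[pid] = {c: False for c in CATEGORY_IDS}
        n_notes = rng.randint(*spec.notes_per_patient)
        note_sentences: list[list[tuple[str, str, str | None]]] = [
            [] for _ in range(n_notes)
        ]

        def plant(note_idx: int, text: str, kind: str,
                  category: str | None) -> None:
            note_sentences[note_idx].append((text, kind, category))
            provenance.append(
                PlantRecord(pid, f"{pid}-n{note_idx}", kind, category, text)
            )

        # Plant one mention sentence per truly fractured site.
        for category in CATEGORY_IDS:
            if rng.random() >= spec.prevalence_for(category):
                continue
            term = rng.choice(vocab[category])
            mod = rng.choice(_MODIFIER_WORDS)
            negated = rng.random() < spec.negation_rate
            if negated:
                template = rng.choice(_NEGATED_TEMPLATES)
                kind = "negated"
            else:
                template = rng.choice(_AFFIRMATIVE_TEMPLATES)
                kind = "affirmative"
                gold[pid][category] = True
            sentence = template.format(mod=mod, term=term)
            sentence = sentence[0].upper() + sentence[1:]
            plant(rng.randrange(n_notes), sentence, kind, category)

        # Hard cases (off by default): planted per patient with the given
        # rate; they exercise the tagger's documented failure modes.
        if spec.hard_case_rate and rng.random() < spec.hard_case_rate:
            category = rng.choice(CATEGORY_IDS)
            term = rng.choice(vocab[category])
            if rng.random() < 0.5:
                text = rng.choice(_COREF_TEMPLATES).format(term=term)
                gold[pid][category] = True  # truly fractured; tagger misses
                kind = "hard_coref"
            else:
                text = rng.choice(_SCOPED_NEGATION_TEMPLATES).format(term=term)
                kind = "hard_scoped_negation"  # truly negative; tagger fires
            plant(rng.randrange(n_notes), text, kind, category)

        # Distractors and neutral padding per note.
        for k in range(n_notes):
            if rng.random() < spec.distractor_rate:
                category = rng.choice(CATEGORY_IDS)
                term = rng.choice(vocab[category])
                sentence = rng.choice(_DISTRACTOR_TEMPLATES).format(term=term)
                plant(k, sentence, "distractor", category)
            plant(k, rng.choice(_NEUTRAL_SENTENCES), "neutral", None)

        # Assemble notes, applying run-on corruption between neighbors.
        # Provenance was recorded at planting time, so merged sentences keep
        # their original kind; each merge adds one extra "runon" record.
        for k, sentences in enumerate(note_sentences):
            rng.shuffle(sentences)
            nid = f"{pid}-n{k}"
            merged: list[str] = []
            for text, _, category in sentences:
                if merged and rng.random() < spec.runon_rate:
                    joined = merged[-1].rstrip(".") + " " + text
                    merged[-1] = joined
                    provenance.append(
                        PlantRecord(pid, nid, "runon", category, joined)
                    )
                else:
                    merged.append(text)
            note_text = " ".join(merged)
            reports.append(
                RadiologyReport(
                    patient_id=pid,
                    note_id=nid,
                    note_type=rng.choice(_NOTE_TYPES),
                    text=note_text,
                )
            )

    return SyntheticCorpus(
        reports=reports, gold=gold, provenance=provenance, spec=spec
    )


def write_provenance_tsv(records: Iterable[PlantRecord], path) -> None:
    """Dump planting provenance for debugging round-trip failures."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id\tnote_id\tkind\tcategory\ttext\n")
        for r in records:
            fh.write(
                f"{r.patient_id}\t{r.note_id}\t{r.kind}\t"
                f"{r.category or ''}\t{r.text}\n"
            )
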