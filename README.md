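# fxtag — rule-based fracture identification in radiology reports

`fxtag` identifies **twenty skeletal site-specific fractures** (ankle,
clavicle, distal forearm, face, feet and toes, hand and fingers, other
spine, patella, pelvis, proximal femur, proximal humerus, ribs, scapula,
shaft and distal femur, shaft and distal humerus, shaft and proximal
radius/ulna, skull, sternum, tibia and fibula, vertebral body) in
free-text radiology reports. It is aimed at EHR phenotyping work —
building patient-level fracture cohorts (e.g. for osteoporosis
surveillance) from the narrative text of X-ray/CT/MRI reports, where the
diagnosis usually lives only in prose.

## The algorithm

Each skeletal site *c* has a regular-expression alternation of site terms
`reFractureCategory(c)` and there is one shared alternation of fracture
modifiers `reFractureModifier` ("fracture(s|d)", "fx(s)", "broken",
"cracked", "displace(d)", "fragment", "separation", "microfracture").
Within every detected sentence, site *c* is asserted iff either
bidirectional rule matches:

```
\b(reFractureModifier)\b .* \b(reFractureCategory)\b
\b(reFractureCategory)\b .* \b(reFractureModifier)\b
```

(word edges are implemented as `(?<!\w) ... (?!\w)` so that terms ending
in punctuation, such as `colles'` or `r/o`, still bind correctly; matching
is case-insensitive). A sentence-scoped **exclusion rule** then suppresses
every mention in a sentence containing one of the keywords
`rule out`, `r/o`, `negative`. A report is positive for a site iff it has
a non-excluded mention; a patient is positive iff any of their reports is
(element-wise OR).

Evaluation against per-patient gold labels uses the five standard metrics
per site *i* and their micro-averages over pooled counts:

```
Sensitivity = TP/(TP+FN)     Specificity = TN/(TN+FP)
PPV = TP/(TP+FP)             NPV = TN/(TN+FN)
F1  = 2·PPV·Sensitivity/(PPV+Sensitivity)
Sensitivity_micro = Σ_i TP_i / Σ_i (TP_i + FN_i)   (etc.)
```

Undefined (0/0) metrics are reported as `NA`, never coerced to 0 or 1.

The package also ships a **synthetic corpus generator** that plants
affirmative, negated, distractor and run-on sentences from the lexicon's
own vocabulary with known gold labels, so the whole pipeline is testable
without access to clinical data. See `docs/methods.md` for the model,
parameter defaults, and known limitations.

## Worked example

```sh
$ cat demo.jsonl
{"patient_id": "p01", "note_id": "n0", "note_type": "X-ray", "text": "Comminuted fracture of the left clavicle. No acute findings elsewhere."}
{"patient_id": "p01", "note_id": "n1", "note_type": "CT", "text": "The bone scan was negative for an acute fracture at that area."}
{"patient_id": "p02", "note_id": "n0", "note_type": "X-ray", "text": "Cannot rule out scaphoid fracture."}

$ fxtag tag --input demo.jsonl --out-labels demo_labels.csv --out-mentions demo_mentions.tsv
tagged 3 notes -> demo_labels.csv
```

`demo_labels.csv` (clavicle and hand columns shown) — patient `p01` is
positive for clavicle only; `p02`'s scaphoid mention was found but
excluded by the `rule out` keyword, so every label stays 0:

```
patient_id,ankle,clavicle,hand_and_fingers
p01,0,1,0
p02,0,0,0
```

`demo_mentions.tsv` keeps the full audit trail, including excluded hits
(spans are character offsets within the sentence):

```
patient_id  note_id  sentence_index  category          ...  order           excluded  exclusion_keyword
p01         n0       0               clavicle          ...  modifier_first  0
p02         n0       0               hand_and_fingers  ...  category_first  1         rule out
```

The other subcommands: `fxtag generate` writes a synthetic corpus plus its
gold labels, `fxtag eval --pred labels.csv --gold gold.csv --out report.csv`
writes the per-site metric table with a final `Micro-Average` row, and
`fxtag lint` reports lexicon diagnostics (e.g. the `navicular` branch is
shared by the feet/toes and hand/fingers sites). The same operations are
available as library functions (`fxtag.tag_corpus`, `fxtag.micro_average`,
`fxtag.generate_corpus`, ...).

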