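import random

import pytest

import fxtag as fx
from conftest import make_sentence, random_sentences
from oracle_utils import oracle_sentence

# In-text example sentences from published failure analyses of the rule
# set; each exercises one behavior of the sentence-scoped rules.
PATIENT_A = (
    "Exam: Fluoro Assistance less < 1hr Indications: left ankle debride "
    "ORIGINAL REPORT ? DATE Mobile image intensifier used."
)
PATIENT_B = (
    "CT examination of the head and maxillofacial bones performed without "
    "IV contrast demonstrates a mildly displaced fracture of the superior "
    "right lamina papyracea."
)
PATIENT_C = (
    "No inflammatory changes to suggest cholecystitis superior endplate "
    "compression fractures of T11 and T12 vertebral body"
)
PATIENT_D = (
    "The bone scan was negative for an acute fracture at that area, "
    "although an acute fracture in the vertebral body of L1 was noted."
)
PATIENT_E = (
    "Cortical irregularity of the dorsal aspect of the distal tuft of the "
    "left thumb. Findings likely represent a small fracture."
)
PATIENT_F = (
    "It does not appear the L1 compression fracture is the cause of her "
    "pain."
)


class TestMatchSentence:
    def test_modifier_then_site(self, matcher):
        s = make_sentence("Comminuted fracture of the left clavicle.")
        (m,) = matcher.match_sentence(s)
        assert m.category == "clavicle"
        assert m.order == "modifier_first"
        assert s.text[slice(*m.modifier_span)].lower() == "fracture"
        assert s.text[slice(*m.category_span)].lower() == "clavicle"
        assert m.modifier_span[1] <= m.category_span[0]

    def test_site_then_modifier(self, matcher):
        s = make_sentence("The clavicle appears fractured.")
        (m,) = matcher.match_sentence(s)
        assert m.category == "clavicle"
        assert m.order == "category_first"

    def test_modifier_first_tie_break(self, matcher):
        s = make_sentence("Fracture of the clavicle, previously fractured.")
        (m,) = matcher.match_sentence(s)
        assert m.order == "modifier_first"

    def test_missing_lexicon_keyword_yields_no_mention(self, matcher):
        # "lamina papyracea" is not in the face patterns and
        # "maxillofacial" contains no word-bounded face term.
        assert matcher.match_sentence(make_sentence(PATIENT_B)) == []

    def test_unlisted_modifier_yields_no_mention(self, matcher):
        # "debride" is not a fracture modifier, so ankle cannot fire.
        assert matcher.match_sentence(make_sentence(PATIENT_A)) == []

    def test_runon_sentence_multi_label(self, matcher):
        cats = {
            m.category for m in matcher.match_sentence(make_sentence(PATIENT_C))
        }
        assert cats == {"vertebral_body", "other_spine"}

    def test_collision_term_fires_both_sites(self, matcher):
        s = make_sentence("Fracture of the navicular.")
        cats = {m.category for m in matcher.match_sentence(s)}
        assert cats == {"feet_and_toes", "hand_and_fingers"}

    def test_one_mention_per_site_per_sentence(self, matcher):
        s = make_sentence("Fracture of the rib and fracture of the ribs.")
        mentions = [
            m for m in matcher.match_sentence(s) if m.category == "ribs"
        ]
        assert len(mentions) == 1

    def test_modifier_alone_no_mention(self, matcher):
        assert (
            matcher.match_sentence(
                make_sentence("Findings likely represent a small fracture.")
            )
            == []
        )

    def test_site_alone_no_mention(self, matcher):
        s = make_sentence(
            "Cortical irregularity of the dorsal aspect of the distal tuft "
            "of the left thumb."
        )
        assert matcher.match_sentence(s) == []


class TestExclusionRules:
    def test_negative_excludes_whole_sentence(self, matcher):
        s = make_sentence(PATIENT_D)
        mentions = matcher.apply_exclusion_rules(matcher.match_sentence(s), s)
        vb = [m for m in mentions if m.category == "vertebral_body"]
        assert vb and vb[0].excluded
        assert vb[0].exclusion_keyword == "negative"

    @pytest.mark.parametrize("kw_text", ["Cannot rule out", "R/o"])
    def test_rule_out_variants_exclude(self, matcher, kw_text):
        s = make_sentence(f"{kw_text} scaphoid fracture.")
        mentions = matcher.apply_exclusion_rules(matcher.match_sentence(s), s)
        (m,) = [m for m in mentions if m.category == "hand_and_fingers"]
        assert m.excluded
        assert m.exclusion_keyword in ("rule out", "r/o")

    def test_no_keyword_retains_mention(self, matcher):
        s = make_sentence("Displaced fracture of the radial head.")
        mentions = matcher.apply_exclusion_rules(matcher.match_sentence(s), s)
        assert mentions and all(not m.excluded for m in mentions)
        assert all(m.exclusion_keyword == "" for m in mentions)

    def test_scoped_negation_phrase_is_not_caught(self, matcher):
        # "does not appear" is outside the printed keyword list, so the
        # mention is retained -- the documented limitation.
        s = make_sentence(PATIENT_F)
        mentions = matcher.apply_exclusion_rules(matcher.match_sentence(s), s)
        vb = [m for m in mentions if m.category == "vertebral_body"]
        assert vb and not vb[0].excluded

    def test_excluded_flag_iff_keyword(self, matcher):
        for text in (PATIENT_D, "Fracture of the rib.", PATIENT_F):
            s = make_sentence(text)
            for m in matcher.apply_exclusion_rules(
                matcher.match_sentence(s), s
            ):
                assert m.excluded == bool(m.exclusion_keyword)

    def test_pre_category_scope_extension(self, patterns, modifiers):
        narrow = fx.RuleMatcher(
            patterns, modifiers, fx.ExclusionConfig(scope="pre_category")
        )
        wide = fx.RuleMatcher(patterns, modifiers)
        s = make_sentence("Acute fracture of the ankle, negative for edema.")
        assert all(
            not m.excluded
            for m in narrow.apply_exclusion_rules(narrow.match_sentence(s), s)
        )
        assert all(
            m.excluded
            for m in wide.apply_exclusion_rules(wide.match_sentence(s), s)
        )

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            fx.ExclusionConfig(scope="paragraph")


class TestTagDocument:
    def test_coreference_across_sentences_is_missed(self, matcher):
        report = fx.RadiologyReport("pE", "n0", "X-ray", PATIENT_E)
        labels, mentions = matcher.tag_document(report)
        assert not any(labels.values())
        assert mentions == []

    def test_fully_excluded_document_keeps_audit_trail(self, matcher):
        report = fx.RadiologyReport(
            "p0", "n0", "X-ray", "Negative for rib fracture."
        )
        labels, mentions = matcher.tag_document(report)
        assert not any(labels.values())
        assert mentions and all(m.excluded for m in mentions)

    def test_empty_text(self, matcher):
        labels, mentions = matcher.tag_document(
            fx.RadiologyReport("p0", "n0", "X-ray", "")
        )
        assert not any(labels.values())
        assert mentions == []

    def test_segmentation_confines_the_gap(self, matcher):
        # Modifier and site in different sentences must not pair up.
        text = "There is a fracture. The ankle is normal."
        labels, _ = matcher.tag_document(
            fx.RadiologyReport("p0", "n0", "X-ray", text)
        )
        assert not labels["ankle"]

    def test_label_true_iff_nonexcluded_mention(self, matcher):
        text = "Fracture of the rib. Negative for ankle fracture."
        labels, mentions = matcher.tag_document(
            fx.RadiologyReport("p0", "n0", "X-ray", text)
        )
        assert labels["ribs"] and not labels["ankle"]
        assert any(m.excluded and m.category == "ankle" for m in mentions)


class TestTagPatient:
    def test_union_across_documents(self, matcher):
        docs = [
            fx.RadiologyReport("p0", "n0", "X-ray", "Fracture of the rib."),
            fx.RadiologyReport("p0", "n1", "CT", "Fracture of the sacrum."),
        ]
        labels, _ = matcher.tag_patient(docs)
        positives = {c for c, v in labels.items() if v}
        assert positives == {"ribs", "pelvis"}

    def test_zero_documents_all_false(self, matcher):
        labels, mentions = matcher.tag_patient([])
        assert not any(labels.values())
        assert mentions == []

    def test_duplicate_documents_idempotent(self, matcher):
        doc = fx.RadiologyReport("p0", "n0", "X-ray", "Fracture of the rib.")
        doc2 = fx.RadiologyReport("p0", "n1", "X-ray", "Fracture of the rib.")
        once, _ = matcher.tag_patient([doc])
        twice, _ = matcher.tag_patient([doc, doc2])
        assert once == twice

    def test_mixed_patients_rejected(self, matcher):
        docs = [
            fx.RadiologyReport("p0", "n0", "X-ray", "x"),
            fx.RadiologyReport("p1", "n0", "X-ray", "x"),
        ]
        with pytest.raises(ValueError, match="p0, p1"):
            matcher.tag_patient(docs)


class TestMatcherProperties:
    def test_oracle_equivalence_sample(self, matcher, patterns, modifiers,
                                       oracle_tables):
        site_exp, mod_exp = oracle_tables
        for text in random_sentences(patterns, modifiers, 300, seed=7):
            s = make_sentence(text)
            got = {m.category: m.order for m in matcher.match_sentence(s)}
            want = oracle_sentence(text, site_exp, mod_exp)
            assert got == want, text

    def test_appending_sentences_is_monotone(self, matcher, patterns,
                                             modifiers):
        rng = random.Random(3)
        base_sentences = random_sentences(patterns, modifiers, 40, seed=5)
        # " fin." terminates every sentence with a token that is neither a
        # modifier, a site term, nor an abbreviation-guard word, so the
        # segmenter recovers exactly the intended sentences.
        for _ in range(25):
            k = rng.randint(0, 4)
            text = " ".join(
                t.rstrip(".") + " fin." for t in rng.sample(base_sentences, k)
            )
            extra = rng.choice(base_sentences).rstrip(".") + " fin."
            before, _ = matcher.tag_document(
                fx.RadiologyReport("p", "n", "X-ray", text)
            )
            after, _ = matcher.tag_document(
                fx.RadiologyReport("p", "n", "X-ray", (text + " " + extra).strip())
            )
            for c in before:
                assert after[c] or not before[c]

    def test_adding_exclusion_keyword_is_monotone(self, matcher, patterns,
                                                  modifiers):
        for text in random_sentences(patterns, modifiers, 120, seed=9):
            s = make_sentence(text)
            n_before = sum(
                not m.excluded
                for m in matcher.apply_exclusion_rules(
                    matcher.match_sentence(s), s
                )
            )
            worse = make_sentence(text + " negative")
            n_after = sum(
                not m.excluded
                for m in matcher.apply_exclusion_rules(
                    matcher.match_sentence(worse), worse
                )
            )
            assert n_after <= n_before

    def test_sentence_order_does_not_change_labels(self, matcher, patterns,
                                                   modifiers):
        rng = random.Random(11)
        sentences = [
            t.rstrip(".") + " fin."
            for t in random_sentences(patterns, modifiers, 8, seed=13)
        ]
        base, _ = matcher.tag_document(
            fx.RadiologyReport("p", "n", "X-ray", " ".join(sentences))
        )
        for _ in range(5):
            shuffled = sentences[:]
            rng.shuffle(shuffled)
            permuted, _ = matcher.tag_document(
                fx.RadiologyReport("p", "n", "X-ray", " ".join(shuffled))
            )
            assert permuted == base


def test_mentions_tsv_audit_columns(matcher, tmp_path):
    report = fx.RadiologyReport("p0", "n0", "X-ray", PATIENT_D)
    _, mentions = matcher.tag_document(report)
    out = tmp_path / "mentions.tsv"
    fx.matcher.write_mentions_tsv(mentions, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t")[:4] == [
        "patient_id", "note_id", "sentence_index", "category",
    ]
    assert len(lines) == 1 + len(mentions)
    assert any("\tnegative" in ln for ln in lines[1:])
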