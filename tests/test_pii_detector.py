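import random

import pytest
from hypothesis import given, strategies as st

from p2pwatch.pii_detector import (
    PiiMatch,
    _structured_patterns,
    detect_geographic,
    detect_organizations,
    detect_person_names,
    detect_structured_ids,
    evaluate_pii_rule,
    harvest_candidate_names,
)
from tests.conftest import make_doc


class TestHarvestCandidateNames:
    def test_following_capture_after_relation(self, triggers):
        doc = make_doc("my daughter Emily went home")
        assert harvest_candidate_names(doc, triggers) == ["Emily"]

    def test_two_names_after_self_identification(self, triggers):
        doc = make_doc("Sincerely, John Smith")
        assert harvest_candidate_names(doc, triggers) == ["John", "Smith"]

    def test_preceding_capture_before_life_event(self, triggers):
        doc = make_doc("Maria Lopez was born on a farm")
        assert harvest_candidate_names(doc, triggers) == ["Maria", "Lopez"]

    def test_no_trigger_no_names(self, triggers):
        assert harvest_candidate_names(make_doc("nothing special here"), triggers) == []

    def test_capture_stops_at_lowercase(self, triggers):
        doc = make_doc("my daughter Emily and her friends")
        assert harvest_candidate_names(doc, triggers) == ["Emily"]

    @given(st.text(alphabet="AbCd efG.,my daughter", max_size=120))
    def test_harvest_subset_of_capitalized_tokens(self, text):
        from p2pwatch.pii_detector import TriggerPatterns, _is_capitalized, _strip_token

        trig = TriggerPatterns.from_file()
        doc = make_doc(text)
        caps = {_strip_token(t) for t in doc.tokens if _is_capitalized(t)}
        assert set(harvest_candidate_names(doc, trig)) <= caps


class TestPersonNames:
    def test_lexicon_first_name(self, name_lexicon):
        doc = make_doc("we met William at the fair")
        hits = detect_person_names(doc, name_lexicon, [])
        assert [(m.subcategory, m.text) for m in hits] == [("first_name", "William")]

    def test_common_misspelling_matches(self, name_lexicon):
        doc = make_doc("signed by Bll yesterday")
        assert any(m.text == "Bll" for m in detect_person_names(doc, name_lexicon, []))

    def test_lowercase_never_matches(self, name_lexicon):
        doc = make_doc("we saw william in town")
        assert detect_person_names(doc, name_lexicon, []) == []

    def test_file_name_list_beats_lexicon_absence(self, name_lexicon):
        doc = make_doc("our guest Xyzara arrived late")
        hits = detect_person_names(doc, name_lexicon, ["Xyzara"])
        assert [(m.subcategory, m.text) for m in hits] == [("relation_name", "Xyzara")]

    def test_sentence_initial_unlisted_word_not_a_match(self, name_lexicon):
        doc = make_doc("Yesterday it rained. Tomorrow it will not.")
        assert detect_person_names(doc, name_lexicon, []) == []


class TestStructuredIds:
    def sub(self, text):
        return [(m.subcategory, m.text) for m in detect_structured_ids(make_doc(text))]

    def test_specific_date_matches(self):
        assert ("date", "March 9th, 1999") in self.sub("born March 9th, 1999 at home")

    def test_month_alone_is_not_specific(self):
        assert self.sub("March was chilly that year") == []

    def test_nineteenth_century_rejected(self):
        assert self.sub("it happened March 9th, 1899 long ago") == []

    def test_numeric_date(self):
        assert ("date", "9/3/1999") in self.sub("the form dated 9/3/1999 was lost")

    def test_obfuscated_email(self):
        assert ("email", "john AT Canada DOT ca") in self.sub(
            "write john AT Canada DOT ca soon"
        )

    def test_plain_email(self):
        assert ("email", "john@canada.ca") in self.sub("send it to john@canada.ca now")

    def test_complete_and_incomplete_phones(self):
        assert ("phone", "(613) 555-1234") in self.sub("call (613) 555-1234 today")
        assert ("phone", "555-1234") in self.sub("call 555-1234 today")

    def test_quebec_health_card(self):
        assert ("health_insurance", "SMIJ 1234 5678") in self.sub(
            "card SMIJ 1234 5678 on file"
        )

    def test_canadian_postal_code_is_geographic(self):
        hits = detect_structured_ids(make_doc("mail to K1A 0B1 please"))
        assert any(
            m.category == "geographic" and m.subcategory == "postal_code"
            for m in hits
        )

    def test_matches_brute_force_scan(self):
        # emulate pattern application at every character offset and compare
        rng = random.Random(7)
        vocab = [
            "hello", "world", "call", "me", "at", "555-0192", "(416)",
            "321-9876", "march", "9th,", "1999", "1899", "12/31/99",
            "j.doe@example.org", "AT", "DOT", "ca", "K1A", "0B1", "90210",
            "SMIJ", "1234", "5678", "wrote", "a", "letter", "9876543210",
        ]
        for _ in range(60):
            tokens = [rng.choice(vocab) for _ in range(rng.randint(1, 100))]
            doc = make_doc(" ".join(tokens))
            got = {
                (m.category, m.subcategory, m.span)
                for m in detect_structured_ids(doc)
            }
            text = " ".join(doc.tokens)
            starts = []
            pos = 0
            for t in doc.tokens:
                starts.append(pos)
                pos += len(t) + 1
            expected = set()
            for category, subcat, pattern, validator in _structured_patterns():
                pos = 0
                while pos <= len(text):
                    m = pattern.search(text, pos)
                    if not m:
                        break
                    pos = m.end() if m.end() > pos else pos + 1
                    if validator is not None and not validator(m):
                        continue
                    lo = max(i for i, s in enumerate(starts) if s <= m.start())
                    hi = max(i for i, s in enumerate(starts) if s < m.end())
                    expected.add((category, subcat, (lo, hi + 1)))
            assert got == expected


class TestGeographic:
    def test_tourist_attraction_tier(self, gazetteer):
        hits = detect_geographic(make_doc("we drove to Banff last fall"), gazetteer)
        assert [(m.subcategory, m.text) for m in hits] == [("place", "Banff")]

    def test_us_place(self, gazetteer):
        hits = detect_geographic(make_doc("he grew up near Springfield back then"), gazetteer)
        assert ("place", "Springfield") in [(m.subcategory, m.text) for m in hits]

    def test_lowercase_country_word_ignored(self, gazetteer):
        assert detect_geographic(make_doc("we had turkey dinner"), gazetteer) == []

    def test_longest_phrase_wins(self, gazetteer):
        hits = detect_geographic(make_doc("flying into New York City tonight"), gazetteer)
        assert [m.text for m in hits] == ["New York City"]

    def test_country_and_capital_tier(self, gazetteer):
        hits = detect_geographic(make_doc("from Paris to France by train"), gazetteer)
        assert {(m.subcategory, m.text) for m in hits} == {
            ("country", "Paris"),
            ("country", "France"),
        }


class TestOrganizations:
    def test_pattern_plus_type(self, org_patterns):
        doc = make_doc("he lived in St. Mary's foster home for years")
        hits = detect_organizations(doc, org_patterns)
        assert len(hits) == 1 and hits[0].subcategory == "organization"

    def test_type_alone_not_enough(self, org_patterns):
        assert detect_organizations(make_doc("the school was closed"), org_patterns) == []

    def test_population_plus_type(self, org_patterns):
        doc = make_doc("the seniors support center on Main")
        assert len(detect_organizations(doc, org_patterns)) == 1

    def test_window_limit(self, org_patterns):
        filler = "word " * 15
        doc = make_doc(f"she lived in town {filler} near the school")
        assert detect_organizations(doc, org_patterns) == []


class TestPiiRule:
    def geo(self, text="Toronto"):
        return PiiMatch("geographic", "place", (0, 1), text)

    def person(self, sub, text):
        return PiiMatch("person", sub, (0, 1), text)

    def test_geo_plus_first_and_last_name(self):
        r = evaluate_pii_rule(
            [self.geo(), self.person("first_name", "John"), self.person("last_name", "Smith")]
        )
        assert r.pii_flag

    def test_geo_alone_insufficient(self):
        assert not evaluate_pii_rule([self.geo()]).pii_flag

    def test_two_identifiers_without_geo_insufficient(self):
        r = evaluate_pii_rule(
            [
                self.person("first_name", "John"),
                PiiMatch("structured", "date", (1, 3), "March 9th, 1999"),
            ]
        )
        assert not r.pii_flag

    def test_repeated_identifier_counts_once(self):
        r = evaluate_pii_rule(
            [
                self.geo(),
                self.person("first_name", "John"),
                self.person("first_name", "John"),
            ]
        )
        assert not r.pii_flag

    def test_first_name_plus_date_of_birth_qualifies(self):
        r = evaluate_pii_rule(
            [
                self.geo(),
                self.person("first_name", "John"),
                PiiMatch("structured", "date", (4, 7), "March 9th, 1999"),
            ]
        )
        assert r.pii_flag

    def test_invalid_subcategory_rejected(self):
        with pytest.raises(ValueError):
            PiiMatch("person", "phone", (0, 1), "x")

    @given(
        st.lists(
            st.sampled_from(
                [
                    PiiMatch("geographic", "place", (0, 1), "Toronto"),
                    PiiMatch("person", "first_name", (1, 2), "John"),
                    PiiMatch("person", "last_name", (2, 3), "Smith"),
                    PiiMatch("structured", "date", (3, 6), "March 9th, 1999"),
                    PiiMatch("structured", "phone", (6, 7), "555-1234"),
                ],
                ),
            max_size=6,
        ),
        st.sampled_from(
            [
                PiiMatch("geographic", "country", (7, 8), "France"),
                PiiMatch("person", "first_name", (8, 9), "Maria"),
                PiiMatch("structured", "email", (9, 10), "a@b.ca"),
            ]
        ),
    )
    def test_flag_monotone_under_match_addition(self, matches, extra):
        before = evaluate_pii_rule(matches).pii_flag
        after = evaluate_pii_rule(list(matches) + [extra]).pii_flag
        assert after or not before


def test_spans_lie_within_document_and_text_matches(
    name_lexicon, triggers, gazetteer, org_patterns
):
    doc = make_doc(
        "Sincerely, John Smith of Toronto, born March 9th, 1999, call "
        "(613) 555-1234 or john AT Canada DOT ca; he lived in the foster "
        "home near K1A 0B1."
    )
    from p2pwatch.pii_detector import detect_all_pii

    result = detect_all_pii(doc, name_lexicon, triggers, gazetteer, org_patterns)
    assert result.pii_flag
    for m in result.matches:
        s, e = m.span
        assert 0 <= s < e <= len(doc.tokens)
        assert m.text == " ".join(doc.tokens[s:e])
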