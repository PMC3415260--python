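import math
import random

import pytest
from hypothesis import given, strategies as st

from p2pwatch.document_model import RawFile
from p2pwatch.resources import resource_path
from p2pwatch.shallow_filters import (
    ContentKeywordSet,
    TitleDatabase,
    build_language_profile,
    detect_publishable_content,
    filter_published_title,
    identify_language,
    remove_duplicates,
)
from tests.conftest import make_doc


def raw(data: bytes, path: str, title: str | None = None) -> RawFile:
    stem = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return RawFile(path, data, math.ceil(len(data) / 1024), "txt", title or stem)


class TestDuplicateRemoval:
    def test_byte_identical_same_name_collapse(self):
        a = raw(b"same content here", "dir1/f.txt")
        b = raw(b"same content here", "dir2/f.txt")
        kept, disc = remove_duplicates([a, b])
        assert len(kept) == 1 and len(disc) == 1
        assert kept[0].path == "dir1/f.txt"  # first in sorted-path order
        assert disc["dir2/f.txt"].stage == "duplicate_removal"

    def test_same_title_and_size_different_content_retained(self):
        a = raw(b"A" * 100, "x/f.txt")
        b = raw(b"B" * 100, "y/f.txt")
        kept, disc = remove_duplicates([a, b])
        assert len(kept) == 2 and not disc

    def test_singleton(self):
        a = raw(b"alone", "f.txt")
        kept, disc = remove_duplicates([a])
        assert kept == [a] and not disc

    def test_idempotent(self):
        files = [raw(b"x" * i, f"f{i % 3}.txt") for i in range(9)]
        kept, _ = remove_duplicates(files)
        again, disc = remove_duplicates(kept)
        assert again == kept and not disc


@pytest.fixture(scope="module")
def db():
    return TitleDatabase.from_file()


class TestTitleFilter:
    def test_published_title_discarded(self, db):
        f = raw(b"text", "The Abominable Snowman.txt")
        disp = filter_published_title(f, db)
        assert disp is not None and disp.stage == "title_filter"

    def test_exemption_word_keeps_file(self):
        db = TitleDatabase(titles={"hospital discharge summary"})
        f = raw(b"text", "x", title="hospital discharge summary")
        assert filter_published_title(f, db) is None

    def test_unknown_title_kept(self, db):
        assert filter_published_title(raw(b"t", "grocery_list_2008.txt"), db) is None

    def test_matching_is_case_and_whitespace_insensitive(self, db):
        f = raw(b"t", "x", title="the  ABOMINABLE   snowman")
        assert filter_published_title(f, db) is not None

    def test_exemption_never_discarded_across_bundled_titles(self, db):
        for word in db.exemption_words:
            for title in list(db.titles)[:10]:
                f = raw(b"t", "x", title=f"{title} {word}")
                assert filter_published_title(f, db) is None


class TestLanguageProfiles:
    def test_single_symbol_dominates(self):
        prof = build_language_profile("aaa", "t", n_range=(1, 1))
        assert prof.ranked_ngrams[0] == "a"

    def test_deterministic(self):
        a = build_language_profile("the quick brown fox", "t")
        b = build_language_profile("the quick brown fox", "t")
        assert a.ranked_ngrams == b.ranked_ngrams

    def test_tie_broken_lexicographically(self):
        prof = build_language_profile("a b", "t", n_range=(1, 1))
        ia, ib = prof.ranked_ngrams.index("a"), prof.ranked_ngrams.index("b")
        assert ia < ib

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            build_language_profile("  12 34  ")


class TestIdentifyLanguage:
    def test_english_paragraph(self, language_profiles, doc_factory):
        doc = doc_factory(
            "The children walked to school in the morning and the teacher "
            "read a story about the sea before lunch was served."
        )
        ranking, is_en = identify_language(doc, language_profiles)
        assert is_en and ranking[0][0] == "en"

    @pytest.mark.parametrize("code", ["fr", "es", "de"])
    def test_training_text_self_match(self, language_profiles, doc_factory, code):
        text = resource_path("lang", f"{code}.txt").read_text(encoding="utf-8")
        ranking, is_en = identify_language(doc_factory(text), language_profiles)
        assert ranking[0][0] == code and not is_en

    def test_short_document_is_unknown(self, language_profiles, doc_factory):
        ranking, is_en = identify_language(doc_factory("too short"), language_profiles)
        assert ranking == [("unknown", 0)] and not is_en

    def test_empty_document_is_unknown(self, language_profiles, doc_factory):
        ranking, is_en = identify_language(doc_factory(""), language_profiles)
        assert ranking[0][0] == "unknown" and not is_en

    def test_requires_english_profile(self, doc_factory, language_profiles):
        non_en = [p for p in language_profiles if p.language_code != "en"]
        with pytest.raises(ValueError):
            identify_language(doc_factory("hello world"), non_en)

    def test_matches_brute_force_oracle(self, language_profiles):
        # independent out-of-place computation on short random documents
        rng = random.Random(99)
        en_words = resource_path("lang", "en.txt").read_text("utf-8").split()
        fr_words = resource_path("lang", "fr.txt").read_text("utf-8").split()
        for _ in range(40):
            pool = en_words if rng.random() < 0.5 else fr_words
            text = " ".join(rng.choice(pool) for _ in range(rng.randint(10, 50)))
            doc = make_doc(text)
            ranking, _ = identify_language(doc, language_profiles, profile_length=400)
            doc_prof = build_language_profile(text, "doc", profile_length=400)
            expected = []
            for lp in language_profiles:
                dist = 0
                for i, g in enumerate(doc_prof.ranked_ngrams):
                    if g in lp.ranked_ngrams:
                        dist += abs(i - lp.ranked_ngrams.index(g))
                    else:
                        dist += 400
                expected.append((lp.language_code, dist))
            expected.sort(key=lambda t: (t[1], t[0]))
            assert ranking == expected


@pytest.fixture(scope="module")
def keywords():
    return ContentKeywordSet.from_file()


class TestContentFilter:
    def test_isbn_is_books(self, keywords, doc_factory):
        doc = doc_factory("This fine ISBN registered volume for sale")
        disp = detect_publishable_content(doc, keywords)
        assert disp is not None and disp.reason.startswith("Books")

    def test_thesis_within_window_is_education(self, keywords, doc_factory):
        text = " ".join(["word"] * 150 + ["thesis"] + ["word"] * 20)
        disp = detect_publishable_content(doc_factory(text), keywords)
        assert disp is not None and disp.reason.startswith("Education")

    def test_keyword_beyond_prefix_ignored(self, keywords, doc_factory):
        text = " ".join(["word"] * 250 + ["thesis"])
        assert detect_publishable_content(doc_factory(text), keywords) is None

    def test_plural_variant_matches(self, keywords, doc_factory):
        doc = doc_factory("a stack of old magazines in the attic")
        disp = detect_publishable_content(doc, keywords)
        assert disp is not None and disp.reason.startswith("Periodical")

    def test_substring_does_not_match(self, keywords, doc_factory):
        # "article" must not fire inside "articulate"
        assert detect_publishable_content(doc_factory("an articulated truck"), keywords) is None

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError):
            ContentKeywordSet(categories={"Books": ["isbn"]})


@given(
    st.lists(
        st.tuples(st.binary(max_size=64), st.sampled_from("abcd"), st.sampled_from("xy")),
        max_size=12,
    )
)
def test_duplicate_removal_monotone_and_idempotent(items):
    files = [
        raw(data, f"{i}/{name}.{suffix}", title=name)
        for i, (data, name, suffix) in enumerate(items)
    ]
    kept, disc = remove_duplicates(files)
    assert len(kept) + len(disc) == len(files)
    assert len(kept) <= len(files)
    again, disc2 = remove_duplicates(kept)
    assert not disc2 and again == kept
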