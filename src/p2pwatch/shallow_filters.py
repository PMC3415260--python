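"""Shallow triage stages: duplicates, published titles, language, publishable content.

These stages discard the bulk of a harvest cheaply, before any deep content
analysis: byte-identical duplicates, files whose title exactly matches a
published-work database, non-English texts (character n-gram language
identification with the out-of-place rank distance), and files whose opening
words carry publishable-content keywords (book/education/retail/periodical/
fictional/politics vocabulary). Published material is assumed not to leak
personal health information, so each filter only removes files it can
guarantee are irrelevant.
"""

from __future__ import annotations

import hashlib
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from p2pwatch.document_model import Disposition, ExtractedDoc, RawFile
from p2pwatch.resources import read_lines, resource_path

__all__ = [
    "TitleDatabase",
    "LanguageProfile",
    "ContentKeywordSet",
    "remove_duplicates",
    "filter_published_title",
    "build_language_profile",
    "identify_language",
    "detect_publishable_content",
    "default_profiles",
    "DEFAULT_EXEMPTION_WORDS",
    "DEFAULT_PROFILE_LENGTH",
    "MIN_LANGUAGE_TOKENS",
]

#: Title-match exemptions: a published-looking title containing one of these
#: words may still be a personal record (a lab report, a discharge summary),
#: so it is retained for deeper analysis.
DEFAULT_EXEMPTION_WORDS = ("notification", "affidavit", "justice", "discharge", "lab")

DEFAULT_PROFILE_LENGTH = 400
DEFAULT_NGRAM_RANGE = (1, 5)
#: Rank distance is meaningless on tiny inputs; shorter documents are
#: classified "unknown" and discarded with the non-English files.
MIN_LANGUAGE_TOKENS = 10


def _normalize_title(title: str) -> str:
    return " ".join(title.casefold().split())


# ---------------------------------------------------------------------------
# duplicate removal

_FINGERPRINT_BYTES = 256


def _duplicate_key(f: RawFile) -> tuple:
    head = hashlib.sha1(f.raw_bytes[:_FINGERPRINT_BYTES]).hexdigest()
    tail = hashlib.sha1(f.raw_bytes[-_FINGERPRINT_BYTES:]).hexdigest()
    return (f.size_kb, _normalize_title(f.title), head, tail)


def remove_duplicates(
    files: list[RawFile],
) -> tuple[list[RawFile], dict[str, Disposition]]:
    """Keep one representative per duplicate group.

    Two files are duplicates when size (in kilobytes), normalized title, and
    the fingerprints of their first and last bytes all agree. The
    representative is the first file in sorted-path order; the rest receive
    discard dispositions at stage ``duplicate_removal``.
    """
    retained: list[RawFile] = []
    discards: dict[str, Disposition] = {}
    seen: dict[tuple, str] = {}
    for f in sorted(files, key=lambda x: x.path):
        key = _duplicate_key(f)
        if key in seen:
            discards[f.path] = Disposition(
                stage="duplicate_removal",
                outcome="discarded",
                reason=f"duplicate of {seen[key]}",
            )
        else:
            seen[key] = f.path
            retained.append(f)
    return retained, discards


# ---------------------------------------------------------------------------
# published-title filter

@dataclass
class TitleDatabase:
    """Local database of published-work titles with exemption words.

    A file whose normalized title exactly matches a database entry is assumed
    to be a published work — unless the title contains an exemption word, in
    which case it is kept for deeper analysis.
    """

    titles: set[str]
    exemption_words: tuple[str, ...] = DEFAULT_EXEMPTION_WORDS

    def __post_init__(self) -> None:
        self.titles = {_normalize_title(t) for t in self.titles}
        self.exemption_words = tuple(w.casefold() for w in self.exemption_words)

    @classmethod
    def from_file(
        cls,
        path: str | Path | None = None,
        exemption_words: tuple[str, ...] = DEFAULT_EXEMPTION_WORDS,
    ) -> "TitleDatabase":
        """Load a one-title-per-line UTF-8 file (default: bundled list)."""
        if path is None:
            lines = read_lines("titles.txt")
        else:
            lines = [
                ln.strip()
                for ln in Path(path).read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        return cls(titles=set(lines), exemption_words=exemption_words)

    def contains(self, title: str) -> bool:
        return _normalize_title(title) in self.titles

    def is_exempt(self, title: str) -> bool:
        words = set(_normalize_title(title).split())
        return any(w in words for w in self.exemption_words)


def filter_published_title(file: RawFile, db: TitleDatabase) -> Disposition | None:
    """Discard a file whose title exactly matches the published-title
    database, unless an exemption word keeps it in play. Returns a discard
    :class:`Disposition` or ``None`` (keep)."""
    if db.contains(file.title) and not db.is_exempt(file.title):
        return Disposition(
            stage="title_filter",
            outcome="discarded",
            reason="title matches published-work database",
        )
    return None


# ---------------------------------------------------------------------------
# language identification (character n-gram rank profiles)

@dataclass(frozen=True)
class LanguageProfile:
    """Rank-ordered character n-gram profile of a language.

    n-grams (n = 1..5, word-boundary padded with ``_``) are ranked most
    frequent first and truncated to a fixed profile length; classification
    compares rank orders, so raw frequencies need not be stored.
    """

    language_code: str
    ranked_ngrams: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ranked_ngrams)) != len(self.ranked_ngrams):
            raise ValueError("profile contains duplicate n-grams")

    @property
    def ranks(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.ranked_ngrams)}

    @classmethod
    def from_file(cls, path: str | Path) -> "LanguageProfile":
        """Load a profile file: one n-gram per line in rank order; the
        filename (without extension) is the language code."""
        p = Path(path)
        grams = [ln for ln in p.read_text(encoding="utf-8").splitlines() if ln]
        return cls(language_code=p.stem, ranked_ngrams=tuple(grams))


_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def _char_ngrams(text: str, n_range: tuple[int, int]) -> Counter:
    """Count word-boundary-padded character n-grams of a text."""
    lo, hi = n_range
    counts: Counter = Counter()
    for word in _WORD_RE.findall(text.casefold()):
        padded = f"_{word}_"
        for n in range(lo, hi + 1):
            for i in range(len(padded) - n + 1):
                counts[padded[i : i + n]] += 1
    return counts


def build_language_profile(
    training_text: str,
    language_code: str = "",
    n_range: tuple[int, int] = DEFAULT_NGRAM_RANGE,
    profile_length: int = DEFAULT_PROFILE_LENGTH,
) -> LanguageProfile:
    """Build a rank profile from training text.

    n-grams are ordered by descending frequency, ties broken
    lexicographically, and the list truncated to ``profile_length``.
    Raises ``ValueError`` on text with no letters.
    """
    counts = _char_ngrams(training_text, n_range)
    if not counts:
        raise ValueError("cannot profile empty text")
    ranked = sorted(counts, key=lambda g: (-counts[g], g))[:profile_length]
    return LanguageProfile(language_code=language_code, ranked_ngrams=tuple(ranked))


def _out_of_place_distance(
    doc: LanguageProfile, lang: LanguageProfile, penalty: int
) -> int:
    """Sum over document n-grams of the rank displacement in the language
    profile; an n-gram absent from the language profile costs the maximum
    penalty (the profile length)."""
    lang_ranks = lang.ranks
    return sum(
        abs(i - lang_ranks[g]) if g in lang_ranks else penalty
        for i, g in enumerate(doc.ranked_ngrams)
    )


def default_profiles(
    profile_length: int = DEFAULT_PROFILE_LENGTH,
) -> list[LanguageProfile]:
    """Profiles built from the bundled training texts (en, fr, es, de)."""
    langs = []
    for code in ("en", "fr", "es", "de"):
        text = resource_path("lang", f"{code}.txt").read_text(encoding="utf-8")
        langs.append(
            build_language_profile(text, code, profile_length=profile_length)
        )
    return langs


def identify_language(
    doc: ExtractedDoc,
    profiles: list[LanguageProfile],
    profile_length: int = DEFAULT_PROFILE_LENGTH,
    min_tokens: int = MIN_LANGUAGE_TOKENS,
) -> tuple[list[tuple[str, int]], bool]:
    """Rank candidate languages for a document.

    Returns ``(ranking, is_english)`` where ranking is a list of
    ``(language_code, distance)`` sorted by ascending out-of-place distance
    (ties by language code) and ``is_english`` is true iff ``"en"`` ranks
    first. Documents shorter than ``min_tokens`` are classified
    ``"unknown"`` with ``is_english`` false.
    """
    if len(profiles) < 2 or not any(p.language_code == "en" for p in profiles):
        raise ValueError("need at least two profiles including 'en'")
    if len(doc.tokens) < min_tokens:
        return [("unknown", 0)], False
    try:
        doc_profile = build_language_profile(
            doc.text, "doc", profile_length=profile_length
        )
    except ValueError:
        return [("unknown", 0)], False
    ranking = sorted(
        (
            (p.language_code, _out_of_place_distance(doc_profile, p, profile_length))
            for p in profiles
        ),
        key=lambda item: (item[1], item[0]),
    )
    return ranking, ranking[0][0] == "en"


# ---------------------------------------------------------------------------
# publishable-content keyword filter

DEFAULT_PREFIX_LEN = 200

_CATEGORIES = ("Books", "Education", "Retail", "Periodical", "Fictional", "Politics")


@dataclass
class ContentKeywordSet:
    """Publishable-content identifier terms, by category.

    Categories cover the vocabulary that marks a file's opening words as a
    published or non-personal text: Books, Education, Retail, Periodical,
    Fictional (incl. celebrities), Politics (incl. public figures).
    """

    categories: dict[str, list[str]]

    def __post_init__(self) -> None:
        missing = [c for c in _CATEGORIES if not self.categories.get(c)]
        if missing:
            raise ValueError(f"empty keyword categories: {missing}")
        self._patterns = {
            cat: [(term, _term_pattern(term)) for term in terms]
            for cat, terms in self.categories.items()
        }

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "ContentKeywordSet":
        """Load a ``category<TAB>term`` file (default: bundled list)."""
        if path is None:
            lines = read_lines("content_keywords.tsv")
        else:
            lines = [
                ln.strip()
                for ln in Path(path).read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        cats: dict[str, list[str]] = {}
        for ln in lines:
            cat, _, term = ln.partition("\t")
            if not term:
                raise ValueError(f"malformed keyword line: {ln!r}")
            cats.setdefault(cat, []).append(term.strip())
        return cls(categories=cats)


def _term_pattern(term: str) -> re.Pattern:
    """Whole-word, case-insensitive pattern for a term and its simple
    plural/singular variants (final word: +s/+es, y→ies)."""
    words = term.split()
    parts = [re.escape(w) for w in words[:-1]]
    last = words[-1]
    if last.endswith("y"):
        last_pat = f"(?:{re.escape(last)}|{re.escape(last[:-1])}ies)"
    else:
        last_pat = f"{re.escape(last)}(?:e?s)?"
    body = r"\s+".join(parts + [last_pat])
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def detect_publishable_content(
    doc: ExtractedDoc,
    keywords: ContentKeywordSet,
    prefix_len: int = DEFAULT_PREFIX_LEN,
) -> Disposition | None:
    """Discard a document whose first ``prefix_len`` words contain a
    publishable-content keyword; the disposition reason names the category
    and term. Returns ``None`` when no keyword occurs in the prefix."""
    prefix = " ".join(doc.tokens[:prefix_len])
    for cat in _CATEGORIES:
        for term, pattern in keywords._patterns.get(cat, []):
            if pattern.search(prefix):
                return Disposition(
                    stage="content_filter",
                    outcome="discarded",
                    reason=f"{cat}: {term}",
                )
    return None
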