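"""Detection of personally identifiable information (PII) in extracted text.

Three identifier families are covered:

* **person** — first/last names from bundled name lexicons, plus capitalized
  words harvested next to trigger phrases (family relations such as
  "my daughter", self-identification such as "sincerely", life events such
  as "was born");
* **structured** — telephone numbers, provincial health insurance numbers,
  specific dates (20th/21st century only), email addresses (including
  obfuscated "AT"/"DOT" forms): deliberately permissive ("soft") regular
  expressions that tolerate format variation;
* **geographic** — gazetteer places at several granularities (countries and
  capitals worldwide; state/province-level detail for the US and Canada),
  postal/ZIP codes, and organizations recognized from an organization-type
  term co-occurring with a language pattern ("lived in") or target
  population ("seniors").

A document counts as PII when it contains at least one geographic identifier
and at least two other distinct personal identifiers (for example a first
name and a last name, or a first name and a date of birth).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from p2pwatch.document_model import ExtractedDoc
from p2pwatch.resources import read_lines

__all__ = [
    "NameLexicon",
    "TriggerPatterns",
    "Gazetteer",
    "OrgPatterns",
    "PiiMatch",
    "PiiResult",
    "harvest_candidate_names",
    "detect_person_names",
    "detect_structured_ids",
    "detect_geographic",
    "detect_organizations",
    "detect_all_pii",
    "evaluate_pii_rule",
    "DEFAULT_HEALTH_CARD_PATTERNS",
]

_CATEGORY_SUBCATS = {
    "person": {"first_name", "last_name", "relation_name"},
    "structured": {"phone", "health_insurance", "date", "email"},
    "geographic": {"postal_code", "country", "place", "organization"},
}

_STRIP_CHARS = string.punctuation + "“”‘’«»…—–"


def _strip_token(tok: str) -> str:
    return tok.strip(_STRIP_CHARS)


def _is_capitalized(tok: str) -> bool:
    t = _strip_token(tok)
    return bool(t) and t[0].isupper() and t[0].isalpha()


@dataclass(frozen=True)
class PiiMatch:
    """One detected identifier, with a 0-based half-open token span."""

    category: str
    subcategory: str
    span: tuple[int, int]
    text: str

    def __post_init__(self) -> None:
        if self.subcategory not in _CATEGORY_SUBCATS.get(self.category, ()):
            raise ValueError(
                f"subcategory {self.subcategory!r} invalid for {self.category!r}"
            )


@dataclass(frozen=True)
class PiiResult:
    """All matches for one document plus the PII decision."""

    matches: tuple[PiiMatch, ...]
    pii_flag: bool


# ---------------------------------------------------------------------------
# lexicons and pattern resources

@dataclass
class NameLexicon:
    """Female-first, male-first and surname lists (formal and informal forms
    plus common misspellings); lookup is case-insensitive, but only
    capitalized document tokens are considered candidates."""

    female_first: frozenset[str]
    male_first: frozenset[str]
    last: frozenset[str]

    @classmethod
    def from_files(
        cls,
        female: str | Path | None = None,
        male: str | Path | None = None,
        last: str | Path | None = None,
    ) -> "NameLexicon":
        def load(path, default):
            if path is None:
                return frozenset(w.casefold() for w in read_lines("names", default))
            return frozenset(
                ln.strip().casefold()
                for ln in Path(path).read_text(encoding="utf-8").splitlines()
                if ln.strip()
            )

        return cls(
            female_first=load(female, "female_first.txt"),
            male_first=load(male, "male_first.txt"),
            last=load(last, "last.txt"),
        )


@dataclass
class TriggerPatterns:
    """Phrases that signal a nearby person name, each with the side
    (preceding/following) on which capitalized words are captured."""

    patterns: list[tuple[str, tuple[str, ...], str]]  # (category, tokens, direction)

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "TriggerPatterns":
        lines = (
            read_lines("triggers.tsv")
            if path is None
            else [
                ln.strip()
                for ln in Path(path).read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        )
        pats = []
        for ln in lines:
            cat, pattern, direction = ln.split("\t")
            if direction not in ("preceding", "following"):
                raise ValueError(f"bad trigger direction in line {ln!r}")
            pats.append((cat, tuple(pattern.casefold().split()), direction))
        # longest pattern first so "my name is" wins over "my name"
        pats.sort(key=lambda p: -len(p[1]))
        return cls(patterns=pats)


@dataclass
class Gazetteer:
    """Geographic names with per-entry granularity tier.

    Tiers: ``country`` and ``capital`` (reported with subcategory
    ``country``); ``us_place``, ``ca_place`` and ``world_city`` (subcategory
    ``place``). Matching is case-sensitive on whole phrases.
    """

    entries: dict[str, str]  # entry -> tier

    def __post_init__(self) -> None:
        if any(not e for e in self.entries):
            raise ValueError("gazetteer entries must be nonempty")
        # index by first token, longest phrases first
        self._by_first: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
        for entry, tier in self.entries.items():
            toks = tuple(_strip_token(t) for t in entry.split())
            self._by_first.setdefault(toks[0], []).append((toks, entry, tier))
        for lst in self._by_first.values():
            lst.sort(key=lambda item: -len(item[0]))

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "Gazetteer":
        lines = (
            read_lines("gazetteer.tsv")
            if path is None
            else [
                ln.strip()
                for ln in Path(path).read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        )
        entries = {}
        for ln in lines:
            entry, _, tier = ln.rpartition("\t")
            entries[entry] = tier
        return cls(entries=entries)


@dataclass
class OrgPatterns:
    """Organization-identifier vocabulary: an organization-type term within a
    token window of a language pattern or target-population term marks an
    organization."""

    language_patterns: list[tuple[str, ...]]
    org_types: list[tuple[str, ...]]
    target_populations: list[tuple[str, ...]]
    window: int = 10

    @classmethod
    def from_file(cls, path: str | Path | None = None, window: int = 10) -> "OrgPatterns":
        lines = (
            read_lines("org_patterns.tsv")
            if path is None
            else [
                ln.strip()
                for ln in Path(path).read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
        )
        buckets: dict[str, list[tuple[str, ...]]] = {
            "language_pattern": [],
            "org_type": [],
            "target_population": [],
        }
        for ln in lines:
            kind, _, term = ln.partition("\t")
            buckets[kind].append(tuple(term.casefold().split()))
        for lst in buckets.values():
            lst.sort(key=len, reverse=True)
        return cls(
            language_patterns=buckets["language_pattern"],
            org_types=buckets["org_type"],
            target_populations=buckets["target_population"],
            window=window,
        )


# ---------------------------------------------------------------------------
# token-sequence helpers

def _norm_tokens(tokens: Sequence[str]) -> list[str]:
    return [_strip_token(t).casefold() for t in tokens]


def _find_phrase(norm: Sequence[str], phrase: tuple[str, ...]) -> list[int]:
    """Start indices where a normalized token phrase occurs."""
    n = len(phrase)
    return [
        i
        for i in range(len(norm) - n + 1)
        if tuple(norm[i : i + n]) == phrase
    ]


def _span_text(tokens: Sequence[str], span: tuple[int, int]) -> str:
    return " ".join(tokens[span[0] : span[1]])


# ---------------------------------------------------------------------------
# person names

_CAPTURE_WINDOW = 2  # capitalized tokens captured per trigger occurrence


def harvest_candidate_names(
    doc: ExtractedDoc, patterns: TriggerPatterns
) -> list[str]:
    """Collect capitalized words adjacent to trigger phrases.

    For each trigger occurrence, up to two capitalized tokens on the
    pattern's declared side are stored (duplicates collapsed, order of first
    appearance). The result is the document's name list, checked before the
    global lexicons during person-name detection.
    """
    tokens = doc.tokens
    norm = _norm_tokens(tokens)
    names: dict[str, None] = {}
    for _cat, phrase, direction in patterns.patterns:
        for start in _find_phrase(norm, phrase):
            if direction == "following":
                idx = range(start + len(phrase), len(tokens))
            else:
                idx = range(start - 1, -1, -1)
            captured = []
            for i in idx:
                if len(captured) >= _CAPTURE_WINDOW:
                    break
                if _is_capitalized(tokens[i]):
                    captured.append(_strip_token(tokens[i]))
                else:
                    break
            if direction == "preceding":
                captured.reverse()
            for name in captured:
                names.setdefault(name, None)
    return list(names)


def detect_person_names(
    doc: ExtractedDoc, lexicon: NameLexicon, names: Iterable[str]
) -> list[PiiMatch]:
    """Match capitalized tokens against the document's harvested name list
    (accepted regardless of the lexicons) and then the name lexicons.

    Subcategory is ``first_name``/``last_name`` per the matching lexicon;
    harvested names absent from every lexicon are ``relation_name``.
    Lowercase tokens never match, so ordinary words shared with name lists
    stay invisible unless capitalized.
    """
    name_list = {n.casefold() for n in names}
    matches = []
    for i, tok in enumerate(doc.tokens):
        if not _is_capitalized(tok):
            continue
        word = _strip_token(tok)
        key = word.casefold()
        subcat = None
        if key in lexicon.female_first or key in lexicon.male_first:
            subcat = "first_name"
        elif key in lexicon.last:
            subcat = "last_name"
        elif key in name_list:
            subcat = "relation_name"
        if subcat is not None:
            matches.append(
                PiiMatch("person", subcat, (i, i + 1), _span_text(doc.tokens, (i, i + 1)))
            )
    return matches


# ---------------------------------------------------------------------------
# structured identifiers (soft regular expressions)

#: Provincial health-card formats, user-replaceable. Ontario: 10 digits with
#: optional 2-letter version code; Quebec: 4 letters + 8 digits; generic
#: 10-digit personal health numbers cover BC and the prairie provinces.
DEFAULT_HEALTH_CARD_PATTERNS: tuple[str, ...] = (
    r"(?<![\dA-Za-z])\d{4}[- ]\d{3}[- ]\d{3}(?:[- ]?[A-Z]{2})?(?![\dA-Za-z])",
    r"(?<![\dA-Za-z])[A-Z]{4}[- ]?\d{4}[- ]?\d{4}(?![\dA-Za-z])",
    r"(?<![\dA-Za-z.-])\d{10}(?![\dA-Za-z.-])",
)

_MONTHS = (
    "january february march april may june july august september october "
    "november december jan feb mar apr jun jul aug sep sept oct nov dec"
).split()
_MONTH_PAT = "|".join(sorted(_MONTHS, key=len, reverse=True))

_PHONE_RE = (
    r"(?<![\d-])(?:\+?1[-. ])?\(\d{3}\)[ .-]?\d{3}[-. ]\d{4}(?![\d-])"
    r"|(?<![\d-])(?:\+?1[-. ])?\d{3}[-. ]\d{3}[-. ]\d{4}(?![\d-])"
    r"|(?<![\d.-])\d{3}[-.]\d{4}(?![\d.-])"
)
_DATE_NUMERIC_RE = (
    r"(?<![\d/-])\d{1,2}[/-]\d{1,2}[/-](\d{4}|\d{2})(?![\d/-])"
)
_DATE_MONTHNAME_RE = (
    rf"\b(?:{_MONTH_PAT})\.?\s+\d{{1,2}}(?:st|nd|rd|th)?(?:\s*,\s*(\d{{4}}))?(?!\d)"
    rf"|\b\d{{1,2}}(?:st|nd|rd|th)?\s+(?:{_MONTH_PAT})\b(?:\s*,?\s*(\d{{4}}))?(?!\d)"
)
_EMAIL_RE = (
    r"[\w.+-]+@[\w-]+(?:\.[\w-]+)+"
    r"|[\w.+-]+\s+AT\s+[\w-]+(?:\s+DOT\s+[\w-]+)+"
)
_POSTAL_RE = (
    r"\b[ABCEGHJ-NPRSTVXYabceghj-nprstvxy]\d[A-Za-z][ -]?\d[A-Za-z]\d\b"
    r"|(?<![\d-])\d{5}(?:-\d{4})?(?![\d-])"
)


def _valid_year_groups(m: re.Match) -> bool:
    """Any captured 4-digit year must fall in 1900–2099."""
    for g in m.groups():
        if g and len(g) == 4 and not (1900 <= int(g) <= 2099):
            return False
    return True


def _structured_patterns(
    health_card_patterns: Sequence[str] = DEFAULT_HEALTH_CARD_PATTERNS,
):
    pats = [
        ("structured", "phone", re.compile(_PHONE_RE), None),
        ("structured", "date", re.compile(_DATE_NUMERIC_RE), _valid_year_groups),
        (
            "structured",
            "date",
            re.compile(_DATE_MONTHNAME_RE, re.IGNORECASE),
            _valid_year_groups,
        ),
        ("structured", "email", re.compile(_EMAIL_RE), None),
        ("geographic", "postal_code", re.compile(_POSTAL_RE), None),
    ]
    for hp in health_card_patterns:
        pats.insert(1, ("structured", "health_insurance", re.compile(hp), None))
    return pats


def _token_offsets(tokens: Sequence[str]) -> tuple[str, list[int]]:
    """Canonical single-spaced text plus the start offset of each token."""
    starts, pos, parts = [], 0, []
    for t in tokens:
        starts.append(pos)
        parts.append(t)
        pos += len(t) + 1
    return " ".join(parts), starts


def _char_to_token_span(
    starts: list[int], tokens: Sequence[str], s: int, e: int
) -> tuple[int, int]:
    lo = 0
    for i, st in enumerate(starts):
        if st <= s:
            lo = i
        else:
            break
    hi = lo
    for j in range(lo, len(starts)):
        if starts[j] < e:
            hi = j
        else:
            break
    return (lo, hi + 1)


def detect_structured_ids(
    doc: ExtractedDoc,
    health_card_patterns: Sequence[str] = DEFAULT_HEALTH_CARD_PATTERNS,
) -> list[PiiMatch]:
    """Scan for phones, health insurance numbers, specific dates, emails and
    postal/ZIP codes with soft regular expressions.

    Dates must be specific (a day, not just a month) and any 4-digit year
    must lie in 1900–2099 — "March 9th, 1999" matches, "March was chilly"
    and "March 9th, 1899" do not. Postal/ZIP hits are reported as geographic
    identifiers; the rest are structured. Spans cover whole tokens.
    """
    text, starts = _token_offsets(doc.tokens)
    matches = []
    seen: set[tuple] = set()
    for category, subcat, pattern, validator in _structured_patterns(
        health_card_patterns
    ):
        for m in pattern.finditer(text):
            if validator is not None and not validator(m):
                continue
            span = _char_to_token_span(starts, doc.tokens, m.start(), m.end())
            key = (category, subcat, span)
            if key in seen:
                continue
            seen.add(key)
            matches.append(
                PiiMatch(category, subcat, span, _span_text(doc.tokens, span))
            )
    matches.sort(key=lambda m: (m.span, m.subcategory))
    return matches


# ---------------------------------------------------------------------------
# geographic identifiers

_TIER_SUBCAT = {
    "country": "country",
    "capital": "country",
    "us_place": "place",
    "ca_place": "place",
    "world_city": "place",
}


def detect_geographic(doc: ExtractedDoc, gaz: Gazetteer) -> list[PiiMatch]:
    """Case-sensitive whole-phrase gazetteer matching, longest phrase first;
    an overlapping shorter place is suppressed ("New York City" beats
    "New York")."""
    tokens = [_strip_token(t) for t in doc.tokens]
    matches = []
    i = 0
    while i < len(tokens):
        hit = None
        for toks, _entry, tier in gaz._by_first.get(tokens[i], ()):
            if tuple(tokens[i : i + len(toks)]) == toks:
                hit = (toks, tier)
                break
        if hit is None:
            i += 1
            continue
        toks, tier = hit
        span = (i, i + len(toks))
        matches.append(
            PiiMatch(
                "geographic",
                _TIER_SUBCAT.get(tier, "place"),
                span,
                _span_text(doc.tokens, span),
            )
        )
        i += len(toks)
    return matches


def detect_organizations(doc: ExtractedDoc, org: OrgPatterns) -> list[PiiMatch]:
    """Mark an organization when an organization-type term falls within the
    configured token window of a language pattern or target-population term;
    the match span covers both."""
    norm = _norm_tokens(doc.tokens)

    def occurrences(phrases):
        occ = []
        for ph in phrases:
            occ.extend((s, s + len(ph)) for s in _find_phrase(norm, ph))
        return occ

    types = occurrences(org.org_types)
    triggers = occurrences(org.language_patterns) + occurrences(
        org.target_populations
    )
    matches = []
    seen: set[tuple[int, int]] = set()
    for ts, te in sorted(types):
        best = None
        for s2, e2 in triggers:
            gap = max(s2 - te, ts - e2, 0)
            if gap <= org.window:
                cand = (min(ts, s2), max(te, e2))
                if best is None or (cand[1] - cand[0]) < (best[1] - best[0]):
                    best = cand
        if best is not None and best not in seen:
            seen.add(best)
            matches.append(
                PiiMatch(
                    "geographic",
                    "organization",
                    best,
                    _span_text(doc.tokens, best),
                )
            )
    return matches


# ---------------------------------------------------------------------------
# decision rule

def _identifier_key(m: PiiMatch) -> tuple[str, str]:
    cleaned = " ".join(
        _strip_token(t).casefold() for t in m.text.split() if _strip_token(t)
    )
    return (m.subcategory, cleaned)


def evaluate_pii_rule(matches: Iterable[PiiMatch]) -> PiiResult:
    """Apply the PII decision rule.

    A document is PII iff it contains at least one geographic identifier and
    at least two other distinct personal identifiers, where distinctness is
    on (subcategory, normalized text): the same string matched twice counts
    once.
    """
    matches = tuple(matches)
    geo = [m for m in matches if m.category == "geographic"]
    others = {
        _identifier_key(m) for m in matches if m.category in ("person", "structured")
    }
    return PiiResult(matches=matches, pii_flag=len(geo) >= 1 and len(others) >= 2)


def detect_all_pii(
    doc: ExtractedDoc,
    lexicon: NameLexicon,
    triggers: TriggerPatterns,
    gaz: Gazetteer,
    org: OrgPatterns,
    health_card_patterns: Sequence[str] = DEFAULT_HEALTH_CARD_PATTERNS,
) -> PiiResult:
    """Run every detector and apply the decision rule."""
    names = harvest_candidate_names(doc, triggers)
    matches: list[PiiMatch] = []
    matches += detect_person_names(doc, lexicon, names)
    matches += detect_structured_ids(doc, health_card_patterns)
    matches += detect_geographic(doc, gaz)
    matches += detect_organizations(doc, org)
    return evaluate_pii_rule(matches)
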