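"""Patient-oriented health information detection and the final PHI decision.

The health lexicon merges several term sources — disease and symptom lists
(the kind derived from ICD and MedDRA), generic and trade drug names (the
kind derived from a national drug product database), and manually collected
acronyms, provider specialties and condition names. Terms are normalized
(lowercased, punctuation and digits removed, stop words eliminated) and
matched longest-first against the identically normalized document token
stream, so "chest pain" wins over a bare "pain".

A file is flagged as personal health information (PHI) only when it is PII
*and* mentions at least ``min_health_terms`` distinct health terms:
identifiers without health specifics ("John Smith caught a cold") are
rejected, as is health vocabulary without an identifiable person.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from p2pwatch.document_model import ExtractedDoc
from p2pwatch.pii_detector import PiiResult
from p2pwatch.resources import read_lines

__all__ = [
    "HealthLexicon",
    "HealthMatch",
    "PhiDecision",
    "build_health_lexicon",
    "load_health_lexicon",
    "detect_health_terms",
    "evaluate_phi",
    "default_stopwords",
    "normalize_term",
]

CATEGORIES = (
    "disease",
    "symptom",
    "procedure",
    "drug_generic",
    "drug_trade",
    "acronym",
    "specialty",
    "condition",
)


def default_stopwords() -> frozenset[str]:
    """The bundled list of ~120 English function words."""
    return frozenset(read_lines("stopwords.txt"))


def normalize_term(raw: str, stopwords: frozenset[str]) -> str:
    """Lowercase, strip punctuation and digits, drop stop words.

    Returns the normalized multi-word term ("Arthritis, rheumatoid" →
    "arthritis rheumatoid", "Vitamin B-12" → "vitamin b") or the empty
    string when nothing survives (a bare stop word, a number).
    """
    cleaned = "".join(
        ch if ch.isalpha() or ch.isspace() else "" for ch in raw.casefold()
    )
    words = [w for w in cleaned.split() if w not in stopwords]
    return " ".join(words)


@dataclass(frozen=True)
class HealthLexicon:
    """Normalized medical terms mapped to their category."""

    terms: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.terms.values()} - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown lexicon categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class HealthMatch:
    """One lexicon hit: normalized term, category, token span in the
    original document."""

    term: str
    category: str
    span: tuple[int, int]


@dataclass(frozen=True)
class PhiDecision:
    """Final decision for one document."""

    pii: PiiResult
    health_matches: tuple[HealthMatch, ...]
    phi_flag: bool


def build_health_lexicon(
    raw_lists: Sequence[tuple[str, Sequence[str]]],
    stopwords: frozenset[str] | None = None,
) -> HealthLexicon:
    """Normalize raw term lists into a :class:`HealthLexicon`.

    ``raw_lists`` pairs a source label (the category) with its raw terms.
    Terms that normalize to the empty string are dropped; a term appearing
    in several sources keeps its first category. Raises ``ValueError`` when
    no sources are given.
    """
    if not raw_lists:
        raise ValueError("no lexicon sources")
    if stopwords is None:
        stopwords = default_stopwords()
    terms: dict[str, str] = {}
    for label, raw_terms in raw_lists:
        for raw in raw_terms:
            norm = normalize_term(raw, stopwords)
            if norm and norm not in terms:
                terms[norm] = label
    return HealthLexicon(terms=terms)


def load_health_lexicon(
    path: str | Path | None = None,
    stopwords: frozenset[str] | None = None,
) -> HealthLexicon:
    """Load a ``term<TAB>category`` source file (default: bundled list) and
    build the lexicon from it."""
    lines = (
        read_lines("health_terms.tsv")
        if path is None
        else [
            ln.strip()
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    )
    by_cat: dict[str, list[str]] = {}
    for ln in lines:
        term, _, cat = ln.rpartition("\t")
        by_cat.setdefault(cat, []).append(term)
    return build_health_lexicon(list(by_cat.items()), stopwords=stopwords)


def detect_health_terms(
    doc: ExtractedDoc,
    lex: HealthLexicon,
    stopwords: frozenset[str] | None = None,
) -> list[HealthMatch]:
    """Longest-match-first whole-word scan of the normalized token stream.

    Document tokens are normalized exactly like lexicon terms (tokens that
    normalize to nothing, including stop words, drop out of the stream but
    keep their position for span reporting). Overlapping shorter matches are
    suppressed.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    stream: list[tuple[str, int]] = []
    for i, tok in enumerate(doc.tokens):
        norm = normalize_term(tok, stopwords)
        if norm:
            stream.append((norm, i))
    if not lex.terms:
        return []
    term_tokens = {t: tuple(t.split()) for t in lex.terms}
    max_len = max(len(tt) for tt in term_tokens.values())
    matches: list[HealthMatch] = []
    p = 0
    while p < len(stream):
        hit = None
        for n in range(min(max_len, len(stream) - p), 0, -1):
            cand = " ".join(w for w, _ in stream[p : p + n])
            if cand in lex.terms:
                hit = (cand, n)
                break
        if hit is None:
            p += 1
            continue
        cand, n = hit
        span = (stream[p][1], stream[p + n - 1][1] + 1)
        matches.append(HealthMatch(term=cand, category=lex.terms[cand], span=span))
        p += n
    return matches


def evaluate_phi(
    pii: PiiResult,
    health: Iterable[HealthMatch],
    min_health_terms: int = 1,
) -> PhiDecision:
    """Combine the PII decision with the health-term evidence.

    ``phi_flag`` requires ``pii.pii_flag`` and at least ``min_health_terms``
    *distinct* health terms.
    """
    health = tuple(health)
    distinct = {m.term for m in health}
    return PhiDecision(
        pii=pii,
        health_matches=health,
        phi_flag=bool(pii.pii_flag and len(distinct) >= min_health_terms),
    )
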