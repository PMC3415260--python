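# Methods

## Problem and model

The scanner decides, for every file in a directory of unknown content,
whether it may disclose personal health information (PHI). A file is PHI
when it identifies a unique individual *and* states specifics of that
individual's health. The decision is decomposed into a conjunction:

* **PII rule** — the file contains ≥ 1 geographic identifier and ≥ 2 other
  distinct personal identifiers (person or structured category). Distinctness
  is on the pair (subcategory, normalized matched text), so the same name
  mentioned twice counts once. Postal/ZIP codes are counted as geographic
  identifiers and telephone numbers as structured ones: several identifier
  types genuinely straddle both families, and a single canonical assignment
  prevents one string from satisfying two slots of the rule at once.
* **Health rule** — the file mentions ≥ `min_health_terms` distinct terms
  from the medical lexicon. The default is 1: the design goal is recall
  (a leak scanner must not miss PHI), and the cost of the resulting
  pseudo-PHI (blank forms, medical CVs, essays) is accepted and deferred to
  manual triage of flagged files. Raising the threshold suppresses
  pseudo-PHI at the price of recall.

Everything before these two rules exists to shrink the candidate set using
only decisions that cannot lose PHI: duplicates (the representative is
kept), exact published titles, non-text files, non-English text, and
publishable content.

## Stage details and numerical choices

**Duplicate removal.** Two files are duplicates when size in kB
(`ceil(bytes/1024)`), case-folded whitespace-collapsed title, and SHA-1
fingerprints of the first and last 256 raw bytes all agree. Fingerprints of
raw bytes, rather than first/last sentences, are used because this stage
runs before text extraction; 256 bytes comfortably covers a first/last
sentence while staying format-agnostic. The representative is the first
file in sorted-path order (deterministic). The stage is idempotent.

**Published-title filter.** "Exact match" is on the normalized title; the
exemption list (*notification, affidavit, justice, discharge, lab*)
whole-word-matches within the title. An exempt title is never discarded,
whatever the database says.

**Text extraction.** Encoding is detected by a byte-level heuristic: BOM,
else strict UTF-8, else Latin-1 — the Latin-1 fallback means no file is
undecodable, matching the policy of processing harvested files as-is with
no normalization. A file is corrupted when its extractor raises or when the
output is < 1% printable characters; both cases are converted to a discard
disposition — extraction never raises to the caller. The extractor registry
maps extensions to callables (built-ins: txt/log/csv, html/htm/xml via
lxml, a minimal hand-written RTF stripper); PDF and Word support is a
registry entry the user supplies, not a core dependency.

**Language identification.** Cavnar–Trenkle rank profiles: character
n-grams (n = 1..5) of word-boundary-padded, case-folded letter tokens,
ranked by descending frequency with lexicographic tie-break, truncated to
profile length 400. Document–language distance is the out-of-place measure;
an n-gram missing from the language profile costs the maximum penalty
(the profile length). Languages are ranked by ascending distance with the
language code as tie-break, and a file survives iff `en` ranks strictly
first. Bundled profiles: en, fr, es, de, built at startup from ~250-word
training texts; users can substitute larger profile files (one n-gram per
line in rank order, filename = language code). Documents under 10 tokens
are classified `unknown` and discarded with the non-English files — rank
distances on shorter inputs are dominated by noise, and a sub-10-token file
cannot satisfy the PII rule's three-identifier minimum anyway.

**Content filter.** Each keyword (six categories: Books, Education, Retail,
Periodical, Fictional — including celebrities — and Politics) is matched
case-insensitively as a whole word within the first 200 whitespace tokens,
with simple plural/singular variants (+s/+es, y→ies) standing in for the
"term variations" a production deployment would enumerate.

**PII detector.**
* Person names: only capitalized tokens are candidates; lookup is
  case-insensitive against female-first, male-first and surname lists. A
  per-document name list is harvested first: for each trigger phrase
  (family relation, self-identification, life event) up to 2 capitalized
  tokens on the declared side are captured — two tokens covers a
  "First Last" signature without runaway capture. Harvested names match
  even when absent from every lexicon.
* Structured identifiers are "soft" regular expressions over the
  single-spaced token stream; matches are mapped to covering token spans.
  Dates must be specific — a day is required, a month alone is not a date —
  and any 4-digit year must fall in 1900–2099 (earlier dates cannot concern
  the health of a living person; an out-of-range year invalidates the whole
  match). Health-card patterns are per-province regexes (Ontario 10-digit
  with optional version code, Quebec 4 letters + 8 digits, generic 10-digit
  PHN) and are user-replaceable through `PipelineConfig`.
* Geographic matching is case-sensitive whole-phrase gazetteer lookup,
  longest phrase first ("New York City" suppresses "New York"); tiers:
  countries/capitals, US state-level places, Canadian province-level places
  and tourist attractions, major world cities. Case sensitivity is what
  keeps "turkey dinner" from matching the country.
* Organizations: an organization-type term within a 10-token window of a
  language pattern ("lived in") or target population ("seniors") yields one
  geographic/organization match covering both.

**Health detector.** Lexicon terms and document tokens share one
normalization: case-fold, delete punctuation and digits, drop stop words
(~120 function words), drop empties. Matching is a longest-first scan of
the normalized stream with overlap suppression ("chest pain" beats "pain");
because stop words drop out of both sides, "shortness of breath" matches as
"shortness breath". Duplicate raw terms keep their first category.

## Audit sampling

`detection_probability(n, θ) = 1 − (1−θ)^n`; `sample_size(θ, P)` returns
the minimal integer n reaching P, computed by the closed form
`⌈ln(1−P)/ln(1−θ)⌉` and then verified (and adjusted if needed) against the
direct evaluation to be immune to floating-point edge cases. At the default
θ = 0.01, P = 0.95 this gives 299; `round_up_to` reproduces the convenient
300 an audit would adopt without conflating rounding with the model.
Stratified draws use Python's deterministic Mersenne-Twister generator
seeded from the plan, sample uniformly without replacement, and return a
stratum whole when it is smaller than n. Samples across strata are disjoint
because the strata partition the discard stages.

## Synthetic corpus generator

The generator emulates the document classes observed in real shared-folder
harvests — PHI letters, pseudo-PHI (forms/CVs/essays), published works,
non-English texts, byte-identical duplicates, binary junk, personal letters
without health content, and health pamphlets without identifiable persons —
as seeded template prose filled from the *packaged* lexicons and
gazetteers, so the intended terminal stage of every file is decidable by
construction and cannot drift when users substitute their own resources.
Duplicates are byte-identical copies placed in subdirectories that sort
after their originals, so the original is always the retained
representative. Generation is a pure function of (spec, seed).

What the generator does **not** emulate: real P2P filename conventions and
size distributions, OCR noise, adversarial obfuscation, negated or
third-party health statements, and the long tail of real-world formats.
Passing the zero-false-negative test on this corpus therefore shows the
pipeline implements its stage contracts exactly; it does not measure recall
on real harvests, which depends on lexicon and gazetteer coverage.

Test and acceptance runs use a 540-file corpus (80 true-PHI, 60 pseudo-PHI,
100 published, 60 each of non-English, duplicates, binary junk, benign
personal and health-only; seed 1234) — large enough to exercise every stage
and class combination while a full run stays around a second.

## Determinism

Files are processed in sorted-path order; reports serialize with sorted
keys; all sampling and generation flows through explicit seeds. Two runs on
identical inputs produce byte-identical JSON reports apart from the
recorded per-stage timings, which are hardware-dependent and excluded from
comparisons. Disabling a stage (e.g. duplicate removal, as a false-negative
audit does) only switches off that stage's rejection: for the PII stage the
detectors still run so downstream evidence stays complete.

## Known limitations

* No coreference or context analysis: a name and a disease in unrelated
  sentences satisfy the PHI rule.
* Pseudo-PHI is flagged, not filtered — separating it automatically is an
  open problem and the report annotates evidence for human triage instead.
* Bundled lists are small stand-ins; production recall requires full name
  databases, gazetteers and ICD/MedDRA/drug-derived term lists.
* English only; non-English files are discarded, not analyzed.
* The binomial audit model assumes independent, identically distributed
  PHI presence across a stratum's files.
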