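# p2pwatch

Users of peer-to-peer file-sharing networks routinely — and usually
unknowingly — expose their shared folders to every other peer. Among the
books, music and homework sit the occasional guardian's note, lawyer's
letter or medical form that discloses **personal health information
(PHI)**: the identity of a person together with specifics of their health.
`p2pwatch` is a scanner for data custodians, privacy officers and
researchers who need to triage large directories of heterogeneous,
unlabeled files and flag the few that may leak PHI, while being able to
*bound* how much the scan might have missed.

## How it works

The scanner is a pipeline of seven stages. The early stages are shallow and
cheap, discarding only files that are guaranteed not to leak PHI; the final
two stages do full content analysis on the small residue:

1. **Duplicate removal** — files agreeing on size (kB), normalized title and
   first/last-bytes fingerprints are collapsed to one representative.
2. **Published-title filter** — a title exactly matching a local database of
   published works is discarded, unless it contains an exemption word
   (*notification, affidavit, justice, discharge, lab*) that suggests a
   personal record.
3. **Text extraction** — markup and formatting meta-information are
   stripped (built-in: txt, HTML/XML, RTF; other formats pluggable);
   non-text and corrupted files are discarded. Extraction never crashes the
   scan, whatever the bytes.
4. **Language identification** — character n-gram rank profiles (n = 1–5,
   profile length 400) compared by the out-of-place distance; files whose
   most likely language is not English are discarded.
5. **Publishable-content filter** — book/education/retail/periodical/
   fictional/politics keywords in the first 200 words mark a file as
   published or non-personal content.
6. **PII detector** — person names (lexicons plus trigger-phrase
   harvesting), structured identifiers (phones, provincial health card
   numbers, specific 20th/21st-century dates, emails including
   `john AT Canada DOT ca` obfuscation, postal/ZIP codes) and geographic
   identifiers (gazetteer places, organizations). A file is PII iff it
   contains **one geographic identifier and two other distinct personal
   identifiers**.
7. **Health detector** — a normalized medical-term lexicon (diseases,
   symptoms, procedures, drugs, acronyms, specialties, conditions) is
   matched longest-first; a PII file with at least one distinct health term
   is flagged as **PHI**.

Flagged files come with complete evidence spans for human review (blank
insurance forms, medical CVs and student essays satisfy the same rule and
are deliberately left to manual triage).

### Bounding the false-negative rate

Discarded files are audited by stratified random sampling under a binomial
model: if each discarded file independently contains PHI with rate θ, a
sample of *n* detects at least one PHI file with probability

    P = 1 − (1 − θ)^n        ⇔        n = ⌈ln(1 − P) / ln(1 − θ)⌉.

At θ = 1% and P = 95% the minimal sample is **n = 299** files per stratum
(the detection probability of a rounded-up sample of 300 is 95.1%). The
default strata group the discard stages: (1) title filter + text extractor
+ language identifier, (2) content filter, (3) PII + health detectors.

## Worked example

Generate a small synthetic harvest (45 files across every document class),
scan it, and draw the audit sample:

```bash
p2pwatch make-fixtures --out demo --seed 7
p2pwatch scan demo --report demo_report.json
```

```
45 files scanned, 10 flagged as PHI
  duplicate_removal: 45 in, 5 discarded
  title_filter: 40 in, 5 discarded
  text_extractor: 35 in, 5 discarded
  language_id: 30 in, 5 discarded
  content_filter: 25 in, 5 discarded
  pii_detector: 20 in, 5 discarded
  health_detector: 15 in, 5 discarded
flagged files:
  demo/form_000.txt
  ...
  demo/letter_004.txt
```

Each stage's `in` count equals the previous stage's `in` minus its
`discarded` count, and discarded + flagged reconciles to the 45 inputs. The
10 flagged files are exactly the generated PHI letters and pseudo-PHI forms
(the generator's manifest, written next to the corpus, records the intended
terminal stage of every file). Then:

```bash
p2pwatch audit-sample --report demo_report.json --theta 0.01 --power 0.95 --seed 1
```

```
per-stratum sample size 299 (theta=0.01, power=0.95, seed=1)
  group1_shallow: 15 files
  group2_content: 5 files
  group3_deep: 10 files
```

With θ = 1% and 95% power the plan asks for 299 files per stratum; strata
smaller than that (as here) are reviewed exhaustively. The CSV manifest
lists the sampled paths per group for manual review.

All of this is available as a library, e.g.:

```python
from p2pwatch import CorpusSpec, generate_corpus, run_pipeline, sample_size

manifest = generate_corpus(CorpusSpec(out_dir="demo", true_phi=5, seed=7))
report = run_pipeline("demo")
print(report.flagged(), sample_size(0.01, 0.95))   # -> [...5 letters...] 299
```

## Substituting real resources

Every bundled list is a deliberately small stand-in: name lexicons,
gazetteer, title database, content keywords, health-term sources, trigger
and organization patterns are plain-text files (one entry per line,
tab-separated where categorized) that can be swapped via `PipelineConfig`
or the YAML config without code changes. See `docs/methods.md` for the
formats, parameters and known limitations.
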