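"""Seeded synthetic corpora that emulate a P2P harvest.

Real shared-folder harvests cannot be redistributed, so every pipeline
stage is exercised on generated documents whose ground truth is decidable
by construction: each document class is built to terminate at one known
stage. Classes:

* ``true_phi`` — personal letters (guardian notes, lawyer's notes) naming a
  person, a place and their health specifics → flagged as PHI;
* ``pseudo_phi`` — blank insurance forms, medical CVs, student essays:
  PII plus health vocabulary but no private disclosure → also flagged
  (separating pseudo-PHI from true PHI is manual triage, not automated);
* ``published`` — a title from the published-title database, or
  publishable-content keywords in the opening words → title/content filter;
* ``non_english`` — French/Spanish prose → language identifier;
* ``duplicates`` — byte-identical copies of other generated files →
  duplicate removal;
* ``binary_junk`` — random media bytes or corrupted control-character
  files → text extractor;
* ``benign_personal`` — full PII but no health term → discarded by the
  health detector;
* ``health_only`` — health terms but not enough identifiers → discarded by
  the PII detector.

Generation is a pure function of (spec, seed): the same spec always yields
byte-identical files. Templates draw only on the packaged lexicons and
gazetteers, so the ground truth cannot drift when users substitute their
own resources.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from p2pwatch.resources import read_lines, resource_path

__all__ = ["CorpusSpec", "generate_corpus", "write_manifest"]


@dataclass
class CorpusSpec:
    """Counts per document class, output directory and RNG seed."""

    out_dir: str
    true_phi: int = 0
    pseudo_phi: int = 0
    published: int = 0
    non_english: int = 0
    duplicates: int = 0
    binary_junk: int = 0
    benign_personal: int = 0
    health_only: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name not in ("out_dir", "seed") and value < 0:
                raise ValueError(f"count {name} must be >= 0")


# word pools, all drawn from the packaged resources ------------------------

def _pools() -> dict:
    gaz = [
        ln.rpartition("\t") for ln in read_lines("gazetteer.tsv")
    ]
    places = [e for e, _, t in gaz if t in ("ca_place", "us_place")]
    health = [ln.rpartition("\t")[0] for ln in read_lines("health_terms.tsv")]
    lower_health = [t for t in health if t == t.lower()]
    titles = read_lines("titles.txt")
    keywords = [ln.split("\t") for ln in read_lines("content_keywords.tsv")]
    return {
        "female": read_lines("names", "female_first.txt"),
        "male": read_lines("names", "male_first.txt"),
        "last": read_lines("names", "last.txt"),
        "places": places,
        "health": lower_health,
        "titles": titles,
        "keywords": keywords,
        "fr": resource_path("lang", "fr.txt").read_text(encoding="utf-8").split(),
        "es": resource_path("lang", "es.txt").read_text(encoding="utf-8").split(),
    }


_MONTHS = (
    "January February March April May June July August September "
    "October November December"
).split()


def _date(rng: random.Random) -> str:
    return (
        f"{rng.choice(_MONTHS)} {rng.randint(1, 28)}, {rng.randint(1940, 2009)}"
    )


def _phone(rng: random.Random) -> str:
    return f"{rng.randint(200, 999)}-555-{rng.randint(1000, 9999)}"


def _true_phi_text(rng: random.Random, pools: dict) -> str:
    first = rng.choice(pools["female"] + pools["male"])
    last = rng.choice(pools["last"])
    place = rng.choice(pools["places"])
    term = rng.choice(pools["health"])
    term2 = rng.choice(pools["health"])
    if rng.random() < 0.5:
        return (
            f"Dear Mrs Walker, while you are looking after the house please "
            f"remember that my daughter {first} {last} takes her medication "
            f"for {term} every evening before bed. She was born {_date(rng)} "
            f"and her clinic in {place} can be reached any weekday. If the "
            f"{term2} gets worse please call the number on the fridge at "
            f"{_phone(rng)} right away. With many thanks for your help while "
            f"we are travelling.\nSincerely, {first} {last}"
        )
    return (
        f"Re: settlement file. Our client {first} {last} of {place} was "
        f"treated for {term} following the accident of {_date(rng)}, and the "
        f"specialist has recommended continued care for the {term2}. Please "
        f"forward the signed records to this office before the end of the "
        f"month so the claim can proceed. You may reach the clerk at "
        f"{_phone(rng)} with questions about the file."
    )


def _pseudo_phi_text(rng: random.Random, pools: dict) -> str:
    first = rng.choice(pools["female"] + pools["male"])
    last = rng.choice(pools["last"])
    place = rng.choice(pools["places"])
    term = rng.choice(pools["health"])
    kind = rng.randrange(3)
    if kind == 0:  # blank insurance form with a worked sample row
        return (
            f"Health benefits claim form. Please print clearly and sign at "
            f"the bottom. Sample entry: {first} {last}, {place}, date of "
            f"birth {_date(rng)}, condition {term}. Leave the remaining "
            f"rows empty until the visit has taken place. Mail the completed "
            f"form to the regional office; allow six weeks for processing."
        )
    if kind == 1:  # medical professional's CV
        return (
            f"Curriculum vitae. {first} {last}, {place}. Telephone "
            f"{_phone(rng)}. Practising {rng.choice(['therapist', 'surgeon'])} "
            f"with a decade of experience in {term} care, seeking a senior "
            f"clinical position. References and certification available on "
            f"request. Willing to relocate anywhere in the province."
        )
    return (  # student essay
        f"For my project this term I interviewed {first} {last}, who moved "
        f"to {place} as a child and later recovered from {term}. Born "
        f"{_date(rng)}, she told me the hardest part was keeping up with "
        f"classmates during treatment. The interview taught me a great deal "
        f"about patience and about how families support one another."
    )


def _benign_text(rng: random.Random, pools: dict) -> str:
    first = rng.choice(pools["female"] + pools["male"])
    last = rng.choice(pools["last"])
    place = rng.choice(pools["places"])
    if rng.random() < 0.5:
        return (
            f"Dear friends, we are delighted to let you know that our family "
            f"is moving to {place} this spring. {first} {last} has accepted "
            f"a position at the bakery on the main street, and the children "
            f"are looking forward to the bigger garden. Our new telephone "
            f"number will be {_phone(rng)} from the first of the month. "
            f"Please come and visit once the boxes are unpacked."
        )
    return (
        f"To whom it may concern, I am writing to recommend {first} {last} "
        f"for the carpentry apprenticeship. He worked with our crew in "
        f"{place} for two summers, arriving early every day, and his joinery "
        f"was always careful and precise. He was born {_date(rng)} and is "
        f"finishing his schooling this year. You may telephone me at "
        f"{_phone(rng)} for further details."
    )


_HEALTH_ONLY_FRAMES = (
    "General advice sheet. Persons recovering from {t1} should rest, drink "
    "plenty of fluids, and avoid heavy lifting until the {t2} has cleared "
    "completely. The pamphlet explains warning signs to watch during "
    "recovery and when a follow-up visit makes sense. There is no charge "
    "for this leaflet and it may be copied freely.",
    "Notes from the public lecture on living well with {t1}. The speaker "
    "described how regular walking, a balanced diet and good sleep reduce "
    "the burden of {t2} for many people. Copies of the slides are available "
    "at the front desk for anyone wanting further reading.",
)


def _health_only_text(rng: random.Random, pools: dict) -> str:
    frame = rng.choice(_HEALTH_ONLY_FRAMES)
    t1 = rng.choice(pools["health"])
    t2 = rng.choice(pools["health"])
    return frame.format(t1=t1, t2=t2)


def _published_keyword_text(rng: random.Random, pools: dict) -> tuple[str, str]:
    cat, term = rng.choice(pools["keywords"])
    return (
        f"This popular {term} edition has been prepared for wide "
        f"distribution and may be shared freely with readers everywhere. "
        f"The collected pages gather the favourite pieces of the last "
        f"decade, together with notes from the editors and a short "
        f"introduction describing how the collection came to be assembled.",
        cat,
    )


def _non_english_text(rng: random.Random, pools: dict) -> str:
    words = pools["fr"] if rng.random() < 0.5 else pools["es"]
    start = rng.randrange(0, len(words) - 60)
    return " ".join(words[start : start + rng.randint(40, 60)])


def _binary_bytes(rng: random.Random) -> tuple[bytes, str]:
    if rng.random() < 0.5:
        return bytes(rng.randrange(256) for _ in range(1024)), "mp3"
    # corrupted "text": almost no printable characters
    return bytes(rng.randrange(0, 9) for _ in range(512)), "txt"


def _wrap_html(text: str) -> bytes:
    body = text.replace("&", "&amp;").replace("<", "&lt;")
    return f"<html><head><title>page</title></head><body><p>{body}</p></body></html>".encode(
        "utf-8"
    )


def _wrap_rtf(text: str) -> bytes:
    body = (
        text.replace("\\", "").replace("{", "").replace("}", "").replace("\n", r"\par ")
    )
    return ("{\\rtf1\\ansi\\deff0 " + body + "}").encode("latin-1")


def generate_corpus(spec: CorpusSpec) -> dict[str, dict[str, str]]:
    """Write the corpus and return the manifest.

    The manifest maps each file path to its class, the stage expected to
    dispose of it, and the expected outcome (``discarded`` or
    ``phi_flagged``). Raises ``OSError`` when the output directory cannot
    be written.
    """
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    pools = _pools()
    manifest: dict[str, dict[str, str]] = {}

    def emit(name: str, data: bytes, cls: str, stage: str, outcome: str) -> Path:
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(data)
        manifest[str(path)] = {
            "class": cls,
            "intended_stage": stage,
            "intended_outcome": outcome,
        }
        return path

    for i in range(spec.true_phi):
        emit(
            f"letter_{i:03d}.txt",
            _true_phi_text(rng, pools).encode("utf-8"),
            "true_phi",
            "health_detector",
            "phi_flagged",
        )
    for i in range(spec.pseudo_phi):
        text = _pseudo_phi_text(rng, pools)
        if i % 3 == 2:
            emit(f"form_{i:03d}.rtf", _wrap_rtf(text), "pseudo_phi",
                 "health_detector", "phi_flagged")
        else:
            emit(f"form_{i:03d}.txt", text.encode("utf-8"), "pseudo_phi",
                 "health_detector", "phi_flagged")
    for i in range(spec.published):
        if i % 2 == 0:  # exact published title
            title = pools["titles"][(i // 2) % len(pools["titles"])]
            sub = f"pub_{i // (2 * len(pools['titles']))}" if i >= 2 * len(
                pools["titles"]
            ) else ""
            name = (f"{sub}/" if sub else "") + f"{title}.txt"
            body = f"shared copy number {i} of a well known work\n".encode("utf-8")
            emit(name, body, "published", "title_filter", "discarded")
        else:  # publishable-content keywords in the opening words
            text, _cat = _published_keyword_text(rng, pools)
            if i % 4 == 1:
                emit(f"book_{i:03d}.html", _wrap_html(text), "published",
                     "content_filter", "discarded")
            else:
                emit(f"book_{i:03d}.txt", text.encode("utf-8"), "published",
                     "content_filter", "discarded")
    for i in range(spec.non_english):
        emit(
            f"texte_{i:03d}.txt",
            _non_english_text(rng, pools).encode("utf-8"),
            "non_english",
            "language_id",
            "discarded",
        )
    for i in range(spec.binary_junk):
        data, ext = _binary_bytes(rng)
        emit(f"track_{i:03d}.{ext}", data, "binary_junk",
             "text_extractor", "discarded")
    for i in range(spec.benign_personal):
        emit(
            f"note_{i:03d}.txt",
            _benign_text(rng, pools).encode("utf-8"),
            "benign_personal",
            "health_detector",
            "discarded",
        )
    for i in range(spec.health_only):
        emit(
            f"pamphlet_{i:03d}.txt",
            _health_only_text(rng, pools).encode("utf-8"),
            "health_only",
            "pii_detector",
            "discarded",
        )

    # byte-identical copies of already generated files, same filename, in
    # subdirectories that sort after the originals
    sources = sorted(manifest)
    for i in range(spec.duplicates):
        if not sources:
            break
        src = Path(sources[i % len(sources)])
        emit(
            f"zz_dup_{i:03d}/{src.name}",
            src.read_bytes(),
            "duplicates",
            "duplicate_removal",
            "discarded",
        )
    return manifest


def write_manifest(manifest: dict[str, dict[str, str]], path: str | Path) -> None:
    """Write the manifest as CSV: path,class,intended_stage,intended_outcome."""
    lines = ["path,class,intended_stage,intended_outcome"]
    for p in sorted(manifest):
        rec = manifest[p]
        lines.append(
            f'"{p}",{rec["class"]},{rec["intended_stage"]},{rec["intended_outcome"]}'
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
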