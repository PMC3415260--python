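"""Seven-stage scan pipeline and its report.

Stage order: duplicate removal → published-title filter → text extraction →
language identification → publishable-content filter → PII detector →
health detector. Shallow stages run first so the expensive content analysis
only ever sees the small residue of files that could possibly leak personal
health information. Every input file ends with exactly one terminal
disposition; flagged files carry their full match evidence for human
triage, discarded files only the stage and reason.

Any stage can be disabled in the configuration (files then shift to the
next stage), which is how a false-negative audit re-runs the scan without,
for example, duplicate removal.
"""

from __future__ import annotations

import csv
import io
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from p2pwatch.document_model import (
    Disposition,
    ExtractedDoc,
    ExtractorRegistry,
    RawFile,
    default_registry,
    extract_text,
    load_file,
)
from p2pwatch.health_detector import (
    default_stopwords,
    detect_health_terms,
    evaluate_phi,
    load_health_lexicon,
)
from p2pwatch.pii_detector import (
    DEFAULT_HEALTH_CARD_PATTERNS,
    Gazetteer,
    NameLexicon,
    OrgPatterns,
    PiiResult,
    TriggerPatterns,
    detect_all_pii,
)
from p2pwatch.shallow_filters import (
    ContentKeywordSet,
    DEFAULT_PREFIX_LEN,
    DEFAULT_PROFILE_LENGTH,
    MIN_LANGUAGE_TOKENS,
    TitleDatabase,
    default_profiles,
    detect_publishable_content,
    filter_published_title,
    identify_language,
    remove_duplicates,
)

__all__ = ["STAGES", "PipelineConfig", "ScanReport", "run_pipeline", "write_report"]

STAGES = (
    "duplicate_removal",
    "title_filter",
    "text_extractor",
    "language_id",
    "content_filter",
    "pii_detector",
    "health_detector",
)


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Path fields default to ``None``, meaning the bundled stand-in resource;
    point them at larger lists to substitute production resources.
    """

    title_db_path: str | None = None
    content_keywords_path: str | None = None
    gazetteer_path: str | None = None
    triggers_path: str | None = None
    org_patterns_path: str | None = None
    health_terms_path: str | None = None
    female_names_path: str | None = None
    male_names_path: str | None = None
    last_names_path: str | None = None
    profile_paths: list[str] = field(default_factory=list)  # n-gram rank files
    min_health_terms: int = 1
    prefix_len: int = DEFAULT_PREFIX_LEN
    profile_length: int = DEFAULT_PROFILE_LENGTH
    min_language_tokens: int = MIN_LANGUAGE_TOKENS
    health_card_patterns: list[str] = field(
        default_factory=lambda: list(DEFAULT_HEALTH_CARD_PATTERNS)
    )
    disabled_stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.disabled_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in disabled_stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def echo(self) -> dict:
        return asdict(self)


class _Resources:
    """All lexicons/gazetteers/profiles loaded once per run."""

    def __init__(self, cfg: PipelineConfig, registry: ExtractorRegistry | None):
        def _load(what, fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except FileNotFoundError as exc:
                raise FileNotFoundError(f"missing {what} resource: {exc}") from exc

        self.registry = registry if registry is not None else default_registry()
        self.title_db = _load("title database", TitleDatabase.from_file, cfg.title_db_path)
        self.keywords = _load(
            "content keywords", ContentKeywordSet.from_file, cfg.content_keywords_path
        )
        self.gazetteer = _load("gazetteer", Gazetteer.from_file, cfg.gazetteer_path)
        self.triggers = _load("trigger patterns", TriggerPatterns.from_file, cfg.triggers_path)
        self.org = _load("organization patterns", OrgPatterns.from_file, cfg.org_patterns_path)
        self.lexicon = _load(
            "name lists",
            NameLexicon.from_files,
            cfg.female_names_path,
            cfg.male_names_path,
            cfg.last_names_path,
        )
        self.health_lex = _load(
            "health terms", load_health_lexicon, cfg.health_terms_path
        )
        self.stopwords = default_stopwords()
        if cfg.profile_paths:
            from p2pwatch.shallow_filters import LanguageProfile

            self.profiles = [
                _load("language profile", LanguageProfile.from_file, p)
                for p in cfg.profile_paths
            ]
        else:
            self.profiles = default_profiles(cfg.profile_length)


@dataclass
class ScanReport:
    """Per-file terminal dispositions, per-stage counts, configuration echo
    and stage timings for one pipeline run."""

    per_file: dict[str, dict]
    stage_counts: dict[str, dict[str, int]]
    config_echo: dict
    timings: dict[str, float]

    def total_files(self) -> int:
        return len(self.per_file)

    def flagged(self) -> list[str]:
        return [p for p, r in self.per_file.items() if r["outcome"] == "phi_flagged"]

    def discarded_by_stage(self, stage: str) -> list[str]:
        return [
            p
            for p, r in self.per_file.items()
            if r["outcome"] == "discarded" and r["stage"] == stage
        ]

    def to_jsonable(self, include_timings: bool = True) -> dict:
        out = {
            "files": [
                {"path": p, **rec} for p, rec in sorted(self.per_file.items())
            ],
            "stage_counts": self.stage_counts,
            "config": self.config_echo,
        }
        if include_timings:
            out["timings"] = self.timings
        return out

    @classmethod
    def from_jsonable(cls, data: dict) -> "ScanReport":
        per_file = {
            rec["path"]: {k: v for k, v in rec.items() if k != "path"}
            for rec in data["files"]
        }
        return cls(
            per_file=per_file,
            stage_counts={k: dict(v) for k, v in data["stage_counts"].items()},
            config_echo=data.get("config", {}),
            timings=dict(data.get("timings", {})),
        )


def _evidence(pii: PiiResult, health_matches) -> list[dict]:
    ev = [
        {
            "kind": "pii",
            "category": m.category,
            "subcategory": m.subcategory,
            "span": list(m.span),
            "text": m.text,
        }
        for m in pii.matches
    ]
    ev += [
        {
            "kind": "health",
            "category": m.category,
            "term": m.term,
            "span": list(m.span),
        }
        for m in health_matches
    ]
    return ev


def run_pipeline(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    registry: ExtractorRegistry | None = None,
) -> ScanReport:
    """Scan every file under ``input_dir`` and return the report.

    Files are processed in sorted-path order, so two runs over the same
    directory and configuration produce identical reports (up to timings).
    A missing resource file aborts at startup naming the file; a failure on
    any individual input never aborts the run.
    """
    cfg = config or PipelineConfig()
    res = _Resources(cfg, registry)
    root = Path(input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory not found: {root}")

    paths = sorted(p for p in root.rglob("*") if p.is_file())
    dispositions: dict[str, Disposition] = {}
    evidence: dict[str, list] = {}
    timings: dict[str, float] = {}
    stage_counts: dict[str, dict[str, int]] = {}
    disabled = set(cfg.disabled_stages)

    files: list[RawFile] = []
    unreadable: set[str] = set()
    for p in paths:
        try:
            files.append(load_file(p))
        except OSError:
            # carried to the text extractor, which owns corrupted inputs
            rf = RawFile(str(p), b"", 0, "", str(p))
            unreadable.add(str(p))
            files.append(rf)

    def _stage(name: str):
        stage_counts[name] = {"input": len(files), "discarded": 0}
        return time.perf_counter()

    def _close(name: str, t0: float, discarded: int):
        stage_counts[name]["discarded"] = discarded
        timings[name] = time.perf_counter() - t0

    # 1. duplicate removal -------------------------------------------------
    t0 = _stage("duplicate_removal")
    if "duplicate_removal" not in disabled:
        files, dup_disc = remove_duplicates(files)
        dispositions.update(dup_disc)
        _close("duplicate_removal", t0, len(dup_disc))
    else:
        files = sorted(files, key=lambda f: f.path)
        _close("duplicate_removal", t0, 0)

    # 2. published-title filter -------------------------------------------
    t0 = _stage("title_filter")
    kept = []
    for f in files:
        disp = (
            filter_published_title(f, res.title_db)
            if "title_filter" not in disabled
            else None
        )
        if disp is None:
            kept.append(f)
        else:
            dispositions[f.path] = disp
    _close("title_filter", t0, len(files) - len(kept))
    files = kept

    # 3. text extraction ---------------------------------------------------
    t0 = _stage("text_extractor")
    docs: list[ExtractedDoc] = []
    n_disc = 0
    for f in files:
        if f.path in unreadable:
            dispositions[f.path] = Disposition(
                "text_extractor", "discarded", "unreadable file"
            )
            n_disc += 1
            continue
        result = extract_text(f, res.registry)
        if isinstance(result, Disposition):
            if "text_extractor" in disabled:
                # stage disabled: carry the file on as an empty document
                docs.append(ExtractedDoc(f, "", (), ()))
            else:
                dispositions[f.path] = result
                n_disc += 1
        else:
            docs.append(result)
    _close("text_extractor", t0, n_disc)

    # 4. language identification ------------------------------------------
    t0 = _stage("language_id")
    stage_counts["language_id"]["input"] = len(docs)
    kept_docs = []
    for doc in docs:
        if "language_id" in disabled:
            kept_docs.append(doc)
            continue
        ranking, is_en = identify_language(
            doc,
            res.profiles,
            profile_length=cfg.profile_length,
            min_tokens=cfg.min_language_tokens,
        )
        if is_en:
            kept_docs.append(doc)
        else:
            dispositions[doc.source.path] = Disposition(
                "language_id",
                "discarded",
                f"most likely language: {ranking[0][0]}",
            )
    _close("language_id", t0, len(docs) - len(kept_docs))
    docs = kept_docs

    # 5. publishable-content filter ---------------------------------------
    t0 = _stage("content_filter")
    stage_counts["content_filter"]["input"] = len(docs)
    kept_docs = []
    for doc in docs:
        disp = (
            detect_publishable_content(doc, res.keywords, cfg.prefix_len)
            if "content_filter" not in disabled
            else None
        )
        if disp is None:
            kept_docs.append(doc)
        else:
            dispositions[doc.source.path] = disp
    _close("content_filter", t0, len(docs) - len(kept_docs))
    docs = kept_docs

    # 6. PII detector ------------------------------------------------------
    t0 = _stage("pii_detector")
    stage_counts["pii_detector"]["input"] = len(docs)
    with_pii: list[tuple[ExtractedDoc, PiiResult]] = []
    n_disc = 0
    for doc in docs:
        pii = detect_all_pii(
            doc,
            res.lexicon,
            res.triggers,
            res.gazetteer,
            res.org,
            cfg.health_card_patterns,
        )
        if "pii_detector" in disabled:
            # rejection criterion off: every file passes as if PII
            pii = PiiResult(matches=pii.matches, pii_flag=True)
        if pii.pii_flag:
            with_pii.append((doc, pii))
        else:
            dispositions[doc.source.path] = Disposition(
                "pii_detector", "discarded", "PII rule not satisfied"
            )
            n_disc += 1
    _close("pii_detector", t0, n_disc)

    # 7. health detector ---------------------------------------------------
    t0 = _stage("health_detector")
    stage_counts["health_detector"]["input"] = len(with_pii)
    n_disc = 0
    for doc, pii in with_pii:
        health = detect_health_terms(doc, res.health_lex, res.stopwords)
        decision = evaluate_phi(pii, health, cfg.min_health_terms)
        if decision.phi_flag or "health_detector" in disabled:
            dispositions[doc.source.path] = Disposition(
                "health_detector",
                "phi_flagged" if decision.phi_flag else "retained",
                f"{len({m.term for m in health})} distinct health terms",
            )
            evidence[doc.source.path] = _evidence(pii, health)
        else:
            dispositions[doc.source.path] = Disposition(
                "health_detector", "discarded", "no patient-oriented health terms"
            )
            n_disc += 1
    _close("health_detector", t0, n_disc)

    per_file = {
        path: {
            "stage": d.stage,
            "outcome": d.outcome,
            "reason": d.reason,
            "evidence": evidence.get(path, []),
        }
        for path, d in sorted(dispositions.items())
    }
    return ScanReport(
        per_file=per_file,
        stage_counts=stage_counts,
        config_echo=cfg.echo(),
        timings=timings,
    )


def write_report(
    report: ScanReport,
    out_path: str | Path,
    format: str = "json",
    include_timings: bool = True,
) -> None:
    """Write a report as schema-stable JSON or one-row-per-file CSV."""
    out = Path(out_path)
    if format == "json":
        out.write_text(
            json.dumps(report.to_jsonable(include_timings), indent=2, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )
    elif format == "csv":
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["path", "stage", "outcome", "reason", "evidence"])
        for path, rec in sorted(report.per_file.items()):
            summary = ";".join(
                f"{e['kind']}:{e.get('subcategory', e.get('term', ''))}"
                f"@{e['span'][0]}-{e['span'][1]}"
                for e in rec["evidence"]
            )
            w.writerow([path, rec["stage"], rec["outcome"], rec["reason"], summary])
        out.write_text(buf.getvalue(), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
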