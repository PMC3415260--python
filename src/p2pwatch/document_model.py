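"""Loading, decoding and text extraction for files of unknown type.

Peer-to-peer shared folders contain arbitrary bytes under arbitrary names:
word-processor documents, web pages, music, half-downloaded junk. This module
turns each file into either an :class:`ExtractedDoc` — plain unicode text with
all markup and formatting meta-information removed — or a discard
:class:`Disposition` when the file is non-text or corrupted. Extraction must
never raise for any input; a scanner that crashes on one malformed file is
useless on a real harvest.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from lxml import etree, html as lxml_html

__all__ = [
    "RawFile",
    "ExtractedDoc",
    "Disposition",
    "ExtractorRegistry",
    "load_file",
    "extract_text",
    "segment",
    "decode_bytes",
    "default_registry",
]

#: Minimum fraction of printable characters for extracted output to count as text.
MIN_PRINTABLE_RATIO = 0.01


@dataclass(frozen=True)
class RawFile:
    """A file as harvested: raw bytes plus the shallow attributes visible
    without extraction (size in kilobytes, lowercase extension, title =
    filename stem)."""

    path: str
    raw_bytes: bytes
    size_kb: int
    extension: str
    title: str

    def __post_init__(self) -> None:
        if self.size_kb != math.ceil(len(self.raw_bytes) / 1024):
            raise ValueError("size_kb must be ceil(byte length / 1024)")


@dataclass(frozen=True)
class ExtractedDoc:
    """Recovered plain text of a file, with whitespace tokens and sentences."""

    source: RawFile
    text: str
    tokens: tuple[str, ...]
    sentences: tuple[str, ...]


@dataclass(frozen=True)
class Disposition:
    """Terminal outcome of one file: which stage discarded it, or whether it
    was retained / flagged as PHI at the end of the pipeline."""

    stage: str
    outcome: str  # "discarded" | "retained" | "phi_flagged"
    reason: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in ("discarded", "retained", "phi_flagged"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def load_file(path: str | Path) -> RawFile:
    """Read a file from disk into a :class:`RawFile`.

    Raises ``OSError`` (naming the path) if the file cannot be read.
    """
    p = Path(path)
    try:
        raw = p.read_bytes()
    except OSError as exc:
        raise OSError(f"cannot read {p}: {exc}") from exc
    title = p.stem
    if not title:  # dotfiles like ".profile": the name is the stem
        title = p.name
    return RawFile(
        path=str(p),
        raw_bytes=raw,
        size_kb=math.ceil(len(raw) / 1024),
        extension=p.suffix.lstrip(".").lower(),
        title=title,
    )


# ---------------------------------------------------------------------------
# decoding

_BOMS = (
    (b"\xef\xbb\xbf", "utf-8-sig"),
    (b"\xff\xfe\x00\x00", "utf-32-le"),
    (b"\x00\x00\xfe\xff", "utf-32-be"),
    (b"\xff\xfe", "utf-16-le"),
    (b"\xfe\xff", "utf-16-be"),
)


def decode_bytes(raw: bytes) -> str:
    """Decode bytes with a byte-level heuristic.

    BOM if present, else strict UTF-8, else Latin-1 — which never fails, so no
    file is undecodable. Files are processed as harvested, with no further
    normalization.
    """
    for bom, codec in _BOMS:
        if raw.startswith(bom):
            try:
                text = raw.decode(codec)
                return text.lstrip("﻿")
            except (UnicodeDecodeError, LookupError):
                break
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


# ---------------------------------------------------------------------------
# extractors

def _extract_txt(raw: bytes) -> str:
    return decode_bytes(raw)


def _extract_html(raw: bytes) -> str:
    text = decode_bytes(raw).strip()
    if not text:
        return ""
    try:
        root = lxml_html.fromstring(text)
    except (etree.ParserError, etree.XMLSyntaxError, ValueError):
        # not even parseable as tag soup: strip tags crudely
        return re.sub(r"<[^>]*>", " ", text)
    return root.text_content()


_RTF_DESTINATIONS = frozenset(
    {"fonttbl", "colortbl", "stylesheet", "info", "pict", "object",
     "header", "footer", "generator", "themedata", "datastore"}
)
_RTF_CONTROL = re.compile(
    r"\\([a-z]{1,32})(-?\d{1,10})? ?|\\'([0-9a-fA-F]{2})|\\([^a-z])|([{}])|([^\\{}]+)",
)
_RTF_SPECIAL = {"par": "\n", "line": "\n", "tab": "\t", "sect": "\n",
                "cell": " ", "row": "\n", "emdash": "—", "endash": "–",
                "lquote": "‘", "rquote": "’",
                "ldblquote": "“", "rdblquote": "”"}


def _extract_rtf(raw: bytes) -> str:
    """Minimal RTF-to-text: drops control words and non-text destination
    groups (font/color tables, embedded pictures), honours \\'hh escapes."""
    text = decode_bytes(raw)
    if not text.lstrip().startswith("{\\rtf"):
        raise ValueError("not an RTF document")
    out: list[str] = []
    skip_depth = 0  # >0 while inside a destination group to ignore
    depth = 0
    for m in _RTF_CONTROL.finditer(text):
        word, _num, hexcode, escchar, brace, literal = (
            m.group(1), m.group(2), m.group(3), m.group(4), m.group(5), m.group(6))
        if brace == "{":
            depth += 1
            if skip_depth:
                continue
            # look ahead for a destination control word
            rest = text[m.end():m.end() + 40]
            dm = re.match(r"\\\*?\\?([a-z]+)", rest)
            if dm and dm.group(1) in _RTF_DESTINATIONS or rest.startswith("\\*"):
                skip_depth = depth
        elif brace == "}":
            if skip_depth and depth == skip_depth:
                skip_depth = 0
            depth = max(depth - 1, 0)
        elif skip_depth:
            continue
        elif word is not None:
            if word in _RTF_SPECIAL:
                out.append(_RTF_SPECIAL[word])
        elif hexcode is not None:
            out.append(bytes([int(hexcode, 16)]).decode("latin-1"))
        elif escchar is not None:
            if escchar in "\\{}":
                out.append(escchar)
            elif escchar == "~":
                out.append(" ")
        elif literal is not None:
            out.append(literal.replace("\r", "").replace("\n", ""))
    return "".join(out)


#: extension -> callable(bytes) -> str
ExtractorRegistry = dict[str, Callable[[bytes], str]]


def default_registry() -> ExtractorRegistry:
    """Built-in extractors: plain text, HTML/XML, RTF.

    Other formats (PDF, Word, ...) are pluggable: register a callable under
    the extension and the pipeline will use it. Unregistered extensions are
    treated as non-text and discarded.
    """
    return {
        "txt": _extract_txt,
        "text": _extract_txt,
        "log": _extract_txt,
        "csv": _extract_txt,
        "html": _extract_html,
        "htm": _extract_html,
        "xml": _extract_html,
        "rtf": _extract_rtf,
    }


_PRINTABLE = frozenset(string.printable) | frozenset(
    chr(c) for c in range(0x00A0, 0x0100)
)


def _printable_ratio(text: str) -> float:
    if not text:
        return 1.0  # empty output is vacuously clean
    printable = sum(1 for ch in text if ch in _PRINTABLE or ch.isprintable())
    return printable / len(text)


def segment(doc_text: str) -> tuple[list[str], list[str]]:
    """Split decoded text into whitespace tokens and sentences.

    Sentences end at terminal punctuation (. ! ?) followed by whitespace; text
    without terminal punctuation is a single sentence. Empty text yields empty
    lists.
    """
    tokens = doc_text.split()
    if not tokens:
        return [], []
    parts = re.split(r"(?<=[.!?])\s+", doc_text.strip())
    sentences = [s for s in (p.strip() for p in parts) if s]
    return tokens, sentences


def extract_text(
    file: RawFile, registry: ExtractorRegistry | None = None
) -> ExtractedDoc | Disposition:
    """Extract plain text from a raw file, or discard it.

    Returns an :class:`ExtractedDoc` on success. Returns a discard
    :class:`Disposition` at stage ``"text_extractor"`` when the extension has
    no registered extractor (non-text media), the extractor raises
    (corrupted), or the output is below the printable-character floor. Never
    raises, whatever the input bytes.
    """
    if registry is None:
        registry = default_registry()
    extractor = registry.get(file.extension)
    if extractor is None:
        return Disposition(
            stage="text_extractor",
            outcome="discarded",
            reason=f"no extractor for extension {file.extension!r}",
        )
    try:
        text = extractor(file.raw_bytes)
    except Exception as exc:  # any extractor failure means a corrupted file
        return Disposition(
            stage="text_extractor",
            outcome="discarded",
            reason=f"extraction failed: {type(exc).__name__}",
        )
    if _printable_ratio(text) < MIN_PRINTABLE_RATIO:
        return Disposition(
            stage="text_extractor",
            outcome="discarded",
            reason="output below printable-character threshold",
        )
    tokens, sentences = segment(text)
    return ExtractedDoc(
        source=file, text=text, tokens=tuple(tokens), sentences=tuple(sentences)
    )
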