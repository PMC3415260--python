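"""Bundled resource lists: small, user-replaceable stand-ins.

Every lexicon, gazetteer and pattern list here is a deliberately small
hand-built list shipped so the scanner works out of the box; each loader in
the sibling modules accepts a path argument so users can substitute larger
resources (full name databases, complete gazetteers, ICD/MedDRA-derived term
lists) without code changes.
"""

from importlib import resources
from pathlib import Path


def resource_path(*parts: str) -> Path:
    """Filesystem path of a bundled resource file."""
    base = resources.files(__name__)
    obj = base.joinpath(*parts)
    return Path(str(obj))


def read_lines(*parts: str) -> list[str]:
    """Non-empty, non-comment lines of a bundled resource file."""
    text = resource_path(*parts).read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
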