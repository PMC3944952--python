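"""Label grammars and normalizers for the four terminologies.

Each scheme writes region labels differently:

* **Talairach Daemon** — five period-separated hierarchy levels
  (hemisphere, lobe, gyrus, tissue type, cell type), e.g.
  ``Right Cerebrum.Temporal Lobe.Inferior Temporal Gyrus.Gray
  Matter.Brodmann area 20``.
* **Desikan-Killiany / FreeSurfer** — hyphenated abbreviation strings
  (``ctx-lh-postcentral``).
* **AAL** — underscore-separated words with a trailing side
  (``Frontal_superior_right``).
* **NeuroLex** — plain English phrases, usually non-lateralized.

Normalization lowercases, expands abbreviations via a per-scheme table,
and pulls the side word out into a laterality attribute, producing a
token sequence comparable across schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml

from .core import Laterality

__all__ = [
    "SchemeId",
    "TalairachLabel",
    "NormalizedLabel",
    "AbbreviationTable",
    "LabelParseError",
    "parse_talairach",
    "normalize_label",
    "default_tables",
]

TALAIRACH_LEVELS = ("hemisphere", "lobe", "gyrus", "tissue", "cell")

#: delimited tokens interpreted as a side marker, per side
LEFT_TOKENS = frozenset({"left", "lh", "l"})
RIGHT_TOKENS = frozenset({"right", "rh", "r"})

#: kept at normalization, dropped only at lexical matching
STOPWORDS = frozenset({"of", "the", "area"})


class LabelParseError(ValueError):
    pass


class SchemeId(str, Enum):
    TALAIRACH = "talairach"
    DK = "dk"
    AAL = "aal"
    NEUROLEX = "neurolex"


_SPLIT_CHARS = {
    SchemeId.TALAIRACH: None,  # whitespace (per-component text)
    SchemeId.DK: "-",
    SchemeId.AAL: "_",
    SchemeId.NEUROLEX: None,
}


@dataclass(frozen=True)
class TalairachLabel:
    """One five-level Talairach Daemon label; ``*`` is a per-level
    wildcard (the daemon emits partial labels)."""

    hemisphere: str
    lobe: str
    gyrus: str
    tissue: str
    cell: str

    @property
    def components(self) -> tuple[str, str, str, str, str]:
        return (self.hemisphere, self.lobe, self.gyrus, self.tissue, self.cell)

    def render(self) -> str:
        return ".".join(self.components)


@dataclass(frozen=True)
class NormalizedLabel:
    scheme: SchemeId
    raw: str
    tokens: tuple[str, ...]
    laterality: Laterality
    warnings: tuple[str, ...] = ()

    def render(self) -> str:
        """Textual form whose re-normalization is a fixed point."""
        side = () if self.laterality is Laterality.UNPAIRED else (self.laterality.value,)
        return " ".join(side + self.tokens)


@dataclass
class AbbreviationTable:
    """Per-scheme token -> expansion phrase map.

    Keys are lowercase; expansion is single-pass, so a table can never
    loop even if an expansion phrase contains another key.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {k.lower(): v for k, v in self.entries.items()}

    def expand(self, token: str) -> Optional[str]:
        return self.entries.get(token.lower())


_BASE_ABBREVIATIONS = {
    "ctx": "cortex",
    "wm": "white matter",
    "gm": "gray matter",
    "sup": "superior",
    "inf": "inferior",
    "mid": "middle",
    "med": "medial",
    "lat": "lateral",
    "ant": "anterior",
    "post": "posterior",
    "gyr": "gyrus",
    "lob": "lobe",
    "ba": "brodmann area",
}


def default_tables() -> dict[SchemeId, AbbreviationTable]:
    """Shipped abbreviation tables (ctx, lh, wm, ... plus common
    positional shorthands); extensible via :func:`load_tables`."""
    return {scheme: AbbreviationTable(dict(_BASE_ABBREVIATIONS))
            for scheme in SchemeId}


def load_tables(path: str | Path) -> dict[SchemeId, AbbreviationTable]:
    """Read per-scheme abbreviation tables from a YAML config.

    Layout: top-level scheme keys, each a token->expansion map; entries
    merge over (and override) the shipped defaults.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    tables = default_tables()
    for scheme_name, entries in data.items():
        scheme = SchemeId(scheme_name)
        merged = dict(tables[scheme].entries)
        merged.update({str(k).lower(): str(v) for k, v in (entries or {}).items()})
        tables[scheme] = AbbreviationTable(merged)
    return tables


def parse_talairach(raw: str) -> TalairachLabel:
    """Parse a period-separated five-level Talairach label.

    Fewer than five components is a parse error unless the trailing
    levels are written as explicit ``*`` wildcards; at least one level
    must be non-wildcard.
    """
    parts = [p.strip() for p in raw.split(".")]
    if len(parts) > 5:
        raise LabelParseError(
            f"{raw!r}: expected 5 period-separated levels, got {len(parts)}")
    if len(parts) < 5:
        raise LabelParseError(
            f"{raw!r}: missing level {len(parts) + 1} "
            f"({TALAIRACH_LEVELS[len(parts)]}); pad with '*' if unlabeled")
    if all(p == "*" for p in parts):
        raise LabelParseError(f"{raw!r}: all five levels are wildcards")
    for i, p in enumerate(parts):
        if not p:
            raise LabelParseError(
                f"{raw!r}: empty level {i + 1} ({TALAIRACH_LEVELS[i]})")
    return TalairachLabel(*parts)


def _tokenize(scheme: SchemeId, raw: str) -> list[str]:
    sep = _SPLIT_CHARS[scheme]
    if sep is None:
        return raw.split()
    # scheme delimiter first, then whitespace inside components, so that
    # a rendered normalized form re-tokenizes identically
    out: list[str] = []
    for piece in raw.split(sep):
        out.extend(piece.split())
    return out


def normalize_label(
    scheme: SchemeId,
    raw: str,
    table: Optional[AbbreviationTable] = None,
) -> NormalizedLabel:
    """Lowercase, split per scheme, expand abbreviations, extract side.

    A delimited token in exactly one of the left/right marker sets sets
    the laterality and is removed from the token list; unknown
    abbreviation-looking tokens pass through verbatim with a warning
    recorded on the result.
    """
    if not raw or not raw.strip():
        raise LabelParseError("empty label")
    scheme = SchemeId(scheme)
    if table is None:
        table = default_tables()[scheme]

    tokens: list[str] = []
    warnings: list[str] = []
    saw_left = saw_right = False
    for tok in _tokenize(scheme, raw):
        low = tok.lower()
        if low in LEFT_TOKENS:
            saw_left = True
            continue
        if low in RIGHT_TOKENS:
            saw_right = True
            continue
        expansion = table.expand(low)
        if expansion is not None:
            tokens.extend(expansion.lower().split())
        else:
            if len(low) <= 3 and low not in STOPWORDS and not low.isdigit():
                warnings.append(
                    f"token {tok!r} looks like an abbreviation but is not "
                    f"in the {scheme.value} table; passed through")
            tokens.append(low)

    if saw_left and saw_right:
        laterality = Laterality.UNPAIRED
        warnings.append("both side markers present; laterality left unpaired")
    elif saw_left:
        laterality = Laterality.LEFT
    elif saw_right:
        laterality = Laterality.RIGHT
    else:
        laterality = Laterality.UNPAIRED

    if not tokens:
        raise LabelParseError(f"{raw!r}: no content tokens after side extraction")
    return NormalizedLabel(scheme=scheme, raw=raw, tokens=tuple(tokens),
                           laterality=laterality, warnings=tuple(warnings))
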