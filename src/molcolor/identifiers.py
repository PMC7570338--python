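"""Ordered compound coloring identifiers.

A compound's identifier is built from its atom color map by grouping atoms
with the same atom identifier, rendering each group as ``(count)[color]``,
sorting the rendered substrings lexicographically, and concatenating:

    (n1)[a1](n2)[a2]...(nk)[ak]

Equal strings across two databases propose a compound correspondence.  Since
atom colors themselves contain parentheses and brackets, the delimiter
characters are backslash-escaped inside ``[...]`` so the string parses
unambiguously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .coloring import AtomColorMap, ColoringConfig, color_compound, color_hash
from .molgraph import MolecularGraph

__all__ = [
    "ColorClass",
    "CompoundIdentifier",
    "CompoundIndex",
    "IdentifierParseError",
    "compound_identifier",
    "parse_identifier",
    "render_classes",
    "build_index",
]

_ESCAPED = "\\()[]"


class ColorClass(NamedTuple):
    color: str
    count: int


class IdentifierParseError(ValueError):
    def __init__(self, message: str, pos: int):
        super().__init__(f"position {pos}: {message}")
        self.pos = pos


def _escape(s: str) -> str:
    out = []
    for ch in s:
        if ch in _ESCAPED:
            out.append("\\")
        out.append(ch)
    return "".join(out)


def _render_one(cls: ColorClass) -> str:
    return f"({cls.count})[{_escape(cls.color)}]"


def render_classes(classes: Iterable[ColorClass]) -> str:
    """Render, sort (whole substrings, counts included) and concatenate."""
    return "".join(sorted(_render_one(c) for c in classes))


@dataclass(frozen=True)
class CompoundIdentifier:
    text: str
    classes: tuple[ColorClass, ...]
    mode: str  # "tight" | "loose"

    @property
    def n_atoms(self) -> int:
        return sum(c.count for c in self.classes)

    @property
    def hash(self) -> str:
        return color_hash(self.text)


def compound_identifier(colors: AtomColorMap, mode: str = "loose") -> CompoundIdentifier:
    """Derive the ordered compound identifier from a finished atom color map.

    One :class:`ColorClass` per distinct atom identifier; atom order in the
    input never matters, so atom-permuted copies of a molecule render the
    same text.
    """
    if not colors.full:
        raise ValueError("empty color map: compound has no colorable atoms")
    counts: dict[str, int] = {}
    for color in colors.full.values():
        counts[color] = counts.get(color, 0) + 1
    rendered = sorted(
        (_render_one(ColorClass(color, n)), ColorClass(color, n))
        for color, n in counts.items()
    )
    classes = tuple(cls for _, cls in rendered)
    return CompoundIdentifier(
        text="".join(sub for sub, _ in rendered), classes=classes, mode=mode
    )


def parse_identifier(text: str) -> list[ColorClass]:
    """Parse ``(n)[color]...`` back into color classes.

    Inverse of :func:`render_classes` on canonical strings; raises
    :class:`IdentifierParseError` with the offending position otherwise.
    """
    classes: list[ColorClass] = []
    i, n = 0, len(text)
    while i < n:
        if text[i] != "(":
            raise IdentifierParseError(f"expected '(' , found {text[i]!r}", i)
        j = text.find(")", i + 1)
        if j < 0:
            raise IdentifierParseError("unterminated count", i)
        digits = text[i + 1:j]
        if not digits.isdigit():
            raise IdentifierParseError(f"count is not a number: {digits!r}", i + 1)
        count = int(digits)
        if count < 1:
            raise IdentifierParseError("count must be >= 1", i + 1)
        i = j + 1
        if i >= n or text[i] != "[":
            raise IdentifierParseError("expected '[' after count", i)
        i += 1
        color_chars: list[str] = []
        while i < n and text[i] != "]":
            if text[i] == "\\":
                if i + 1 >= n:
                    raise IdentifierParseError("dangling escape", i)
                color_chars.append(text[i + 1])
                i += 2
            else:
                color_chars.append(text[i])
                i += 1
        if i >= n:
            raise IdentifierParseError("unterminated color", i)
        i += 1  # past ']'
        classes.append(ColorClass("".join(color_chars), count))
    if not classes:
        raise IdentifierParseError("empty identifier", 0)
    return classes


@dataclass
class CompoundIndex:
    """Compound collection keyed by compound identifier text.

    ``mapping`` sends identifier text -> sorted compound ids; any value of
    length > 1 is a within-database ambiguity (several compounds sharing an
    identifier at this specificity).  ``failures`` records compounds whose
    coloring raised, with the message.
    """

    mode: str
    mapping: dict[str, list[str]]
    failures: dict[str, str]

    def ambiguous(self) -> dict[str, list[str]]:
        return {k: v for k, v in self.mapping.items() if len(v) > 1}


def build_index(
    compounds: Iterable[tuple[str, MolecularGraph]],
    cfg: ColoringConfig | None = None,
) -> CompoundIndex:
    """Color every compound (graphs are expected pre-normalized) and index by
    identifier text.  Coloring failures are warned about and skipped, never
    fatal."""
    cfg = cfg or ColoringConfig.loose()
    mapping: dict[str, list[str]] = {}
    failures: dict[str, str] = {}
    for cid, graph in compounds:
        try:
            ident = compound_identifier(color_compound(graph, cfg), mode=cfg.mode)
        except Exception as exc:  # noqa: BLE001 - per-compound isolation
            warnings.warn(f"coloring failed for {cid}: {exc}", stacklevel=2)
            failures[cid] = str(exc)
            continue
        mapping.setdefault(ident.text, []).append(cid)
    for ids in mapping.values():
        ids.sort()
    return CompoundIndex(mode=cfg.mode, mapping=mapping, failures=failures)
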