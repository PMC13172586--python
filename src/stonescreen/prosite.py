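"""PROSITE-syntax motif patterns: parsing and matching.

Supports the pattern elements needed for motif scanning: a literal residue,
an allowed set ``[ABC]``, an excluded set ``{ABC}``, the wildcard ``x``, and
repeat counts ``(n)`` or ranges ``(n,m)`` attached to any element. Elements
are separated by ``-``; a trailing ``.`` is tolerated. Anchors (``<``, ``>``)
are not supported and raise a parse error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)


class PatternSyntaxError(ValueError):
    """Raised when a PROSITE pattern does not parse; names the bad element."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: a residue set repeated min_repeat..max_repeat times."""

    allowed: frozenset
    min_repeat: int = 1
    max_repeat: int = 1

    @property
    def fixed(self) -> bool:
        return self.min_repeat == self.max_repeat


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str
    elements: tuple = field(default_factory=tuple)

    @property
    def fixed_length(self) -> bool:
        return all(e.fixed for e in self.elements)

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str, pattern: str) -> PatternElement:
    body = token
    lo = hi = 1
    m = _REPEAT_RE.search(token)
    if m:
        body = token[: m.start()]
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if lo < 0 or hi < lo or hi < 1:
            raise PatternSyntaxError(
                f"pattern {pattern!r}: bad repeat in element {token!r}"
            )
    elif "(" in token or ")" in token:
        raise PatternSyntaxError(
            f"pattern {pattern!r}: unbalanced repeat in element {token!r}"
        )
    if body == "x":
        allowed = _STANDARD_SET
    elif len(body) == 1 and body in _STANDARD_SET:
        allowed = frozenset(body)
    elif body.startswith("[") and body.endswith("]") and len(body) > 2:
        members = body[1:-1]
        if not set(members) <= _STANDARD_SET:
            raise PatternSyntaxError(
                f"pattern {pattern!r}: non-standard residue in element {token!r}"
            )
        allowed = frozenset(members)
    elif body.startswith("{") and body.endswith("}") and len(body) > 2:
        members = body[1:-1]
        if not set(members) <= _STANDARD_SET:
            raise PatternSyntaxError(
                f"pattern {pattern!r}: non-standard residue in element {token!r}"
            )
        allowed = _STANDARD_SET - frozenset(members)
    else:
        raise PatternSyntaxError(f"pattern {pattern!r}: cannot parse element {token!r}")
    return PatternElement(allowed=allowed, min_repeat=lo, max_repeat=hi)


def parse_pattern(text: str, name: str = "") -> MotifPattern:
    """Parse a PROSITE-syntax pattern string into a :class:`MotifPattern`."""
    stripped = text.strip().rstrip(".")
    if not stripped:
        raise PatternSyntaxError("empty pattern")
    elements = tuple(_parse_element(tok, stripped) for tok in stripped.split("-"))
    return MotifPattern(name=name, pattern=stripped, elements=elements)


def match_ends(sequence: str, start: int, elements) -> list:
    """All 0-based exclusive end positions of matches anchored at ``start``.

    Ends are returned sorted ascending (shortest match first).
    """
    positions = {start}
    for elem in elements:
        nxt = set()
        for pos in positions:
            if elem.min_repeat == 0:
                nxt.add(pos)
            run = 0
            while (
                run < elem.max_repeat
                and pos + run < len(sequence)
                and sequence[pos + run] in elem.allowed
            ):
                run += 1
                if run >= elem.min_repeat:
                    nxt.add(pos + run)
        positions = nxt
        if not positions:
            return []
    return sorted(positions)


def to_regex(pattern: MotifPattern) -> str:
    """Translate a pattern to an equivalent Python regular expression."""
    parts = []
    for elem in pattern.elements:
        if len(elem.allowed) == len(_STANDARD_SET):
            cls = f"[{STANDARD_RESIDUES}]"
        elif len(elem.allowed) == 1:
            cls = next(iter(elem.allowed))
        else:
            cls = "[" + "".join(sorted(elem.allowed)) + "]"
        if elem.fixed:
            parts.append(cls if elem.min_repeat == 1 else f"{cls}{{{elem.min_repeat}}}")
        else:
            parts.append(f"{cls}{{{elem.min_repeat},{elem.max_repeat}}}")
    return "".join(parts)
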