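"""HLA allele names, amino-acid motif specifiers and position labels.

An HLA allele name is ``<locus>*<field>[:<field>...]<suffix?>`` with one to
four colon-separated numeric fields (allele family, protein, synonymous,
non-coding) and an optional single-letter expression suffix (N, L, S, C, A,
Q).  Names may carry an ``HLA-`` prefix, which is preserved verbatim.

Alignment columns are addressed by *position labels*: integers (negative for
positions upstream of the mature protein / gene start, with no position 0)
and fractional insertion labels ``n.k`` for the k-th inserted column after
position n.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

_ALLELE_RE = re.compile(
    r"^(?P<prefix>HLA-)?"
    r"(?P<locus>[A-Z][A-Za-z0-9]*)\*"
    r"(?P<fields>\d+(?::\d+){0,3})"
    r"(?P<suffix>[NLSCAQ])?$"
)


class AlleleNameError(ValueError):
    """Raised when a string cannot be parsed as an HLA allele name."""


@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele name.

    Attributes
    ----------
    locus:
        Gene symbol without the ``HLA-`` prefix, e.g. ``"DRB1"``.
    fields:
        One to four numeric field strings, e.g. ``("13", "07")``.
    suffix:
        Optional expression suffix character (one of N, L, S, C, A, Q).
    prefix:
        ``"HLA-"`` if the original string carried the prefix, else ``""``.
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str | None = None
    prefix: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"allele name needs 1-4 fields, got {len(self.fields)}"
            )
        if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleNameError(f"illegal expression suffix {self.suffix!r}")

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise AlleleNameError(f"not a valid HLA allele name: {text!r}")
        return cls(
            locus=m.group("locus"),
            fields=tuple(m.group("fields").split(":")),
            suffix=m.group("suffix"),
            prefix=m.group("prefix") or "",
        )

    @property
    def raw(self) -> str:
        """The rendered name; parse/render round-trips exactly."""
        return (
            self.prefix
            + self.locus
            + "*"
            + ":".join(self.fields)
            + (self.suffix or "")
        )

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    def truncate(self, k: int) -> "AlleleName":
        """Truncate to ``k`` fields, preserving the expression suffix.

        ``B*13:07:01N`` truncated to two fields is ``B*13:07N``: a null (or
        otherwise suffixed) allele stays recognisable at lower resolution.
        """
        if k < 1:
            raise AlleleNameError("cannot truncate to fewer than 1 field")
        if k >= len(self.fields):
            return self
        return replace(self, fields=self.fields[:k])

    def without_prefix(self) -> "AlleleName":
        return replace(self, prefix="") if self.prefix else self

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw


# ---------------------------------------------------------------------------
# position labels


def label_key(label: str | int | float) -> tuple[int, int]:
    """Sort key for a position label: (integer part, insertion sub-index).

    ``"25"`` -> (25, 0); ``"25.2"`` -> (25, 2); ``"-3"`` -> (-3, 0).
    """
    s = str(label)
    if "." in s:
        head, sub = s.split(".", 1)
        return int(head), int(sub)
    return int(s), 0


def format_label(integer: int, sub: int = 0) -> str:
    return str(integer) if sub == 0 else f"{integer}.{sub}"


def next_position(pos: int, step: int = 1) -> int:
    """Advance an alignment position, skipping 0 (there is no position 0)."""
    nxt = pos + step
    if pos < 0 <= nxt or (step < 0 and nxt == 0):
        nxt += step
    return nxt if nxt != 0 else nxt + step


# ---------------------------------------------------------------------------
# motifs

_MOTIF_SEPS = re.compile(r"[~∼]")  # ASCII tilde or U+223C TILDE OPERATOR


class MotifError(ValueError):
    """Raised for malformed amino-acid motif specifiers."""


@dataclass(frozen=True)
class MotifSpec:
    """A locus-anchored residue motif, e.g. ``DRB1*25R~38V~48R~127I``.

    ``terms`` is an ordered list of ``(position_label, residue)`` pairs with
    strictly increasing positions.  Both ``~`` and the typographic tilde
    (U+223C) are accepted as separators on input; rendering always emits
    ASCII ``~``.
    """

    locus: str
    terms: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.terms:
            raise MotifError("motif needs at least one position~residue term")
        keys = [label_key(p) for p, _ in self.terms]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise MotifError("motif positions must be strictly increasing")

    @classmethod
    def parse(cls, text: str) -> "MotifSpec":
        text = text.strip()
        if "*" not in text:
            raise MotifError(f"motif must be '<locus>*<terms>': {text!r}")
        locus, _, body = text.partition("*")
        terms = []
        for token in _MOTIF_SEPS.split(body):
            m = re.match(r"^(-?\d+(?:\.\d+)?)([A-Za-z.*])$", token.strip())
            if m is None:
                raise MotifError(f"bad motif term {token!r} in {text!r}")
            terms.append((m.group(1), m.group(2).upper()))
        return cls(locus=locus.removeprefix("HLA-"), terms=tuple(terms))

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.terms)

    def render(self) -> str:
        return self.locus + "*" + "~".join(p + r for p, r in self.terms)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def sort_allele_names(names: Iterable[str]) -> list[str]:
    """Deterministic lexicographic-by-field ordering of allele name strings."""

    def key(raw: str):
        a = AlleleName.parse(raw)
        return (a.locus, tuple(int(f) for f in a.fields), a.suffix or "")

    return sorted(names, key=key)
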