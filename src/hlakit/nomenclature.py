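"""Allele-name validation and cross-release translation.

IPD-IMGT/HLA allele names change between quarterly releases (renames,
deletions, field extensions), but each sequence keeps a stable accession.
The allele-list history maps accession x release -> current name, which
makes translation mechanical: look the name up in the source release, find
its accession, and read off the accession's name in the target release.

The same leaf-level translation is lifted to GL Strings (delimited
multi-locus genotype encodings: ``^`` between genes, ``|`` between
genotypes, ``+`` within a genotype, ``~`` for phase, ``/`` for allelic
ambiguity), GL String Codes (``namespace#version#glstring``) and whole
tabular genotype datasets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Literal

import pandas as pd

from .imgt_io import AlleleHistory
from .names import AlleleName, AlleleNameError, sort_allele_names

OnMissing = Literal["drop", "keep", "fail"]


class TranslationError(ValueError):
    pass


class InvalidAlleleError(TranslationError):
    """The name does not occur in the source release (distinct from a name
    that exists there but has no counterpart in the target release)."""


class AmbiguousTranslationError(TranslationError):
    """A truncated name expands to several full names whose translations
    disagree after re-truncation."""


# ---------------------------------------------------------------------------
# verification and queries


def verify_allele(
    name: str | AlleleName, release: str, history: AlleleHistory
) -> tuple[bool, str | None]:
    """Is this exact name current in ``release``?  Returns (valid, accession).

    A string that is not a well-formed allele name raises
    :class:`~hlakit.names.AlleleNameError` - malformed is not the same as
    absent.
    """
    allele = AlleleName.parse(name) if isinstance(name, str) else name
    acc = history.names_in(release).get(allele.without_prefix().raw)
    return acc is not None, acc


def query_release(
    history: AlleleHistory,
    release: str,
    pattern: str,
    count_only: bool = False,
) -> list[str] | int:
    """Allele names in one release matching a locus, prefix or substring."""
    names = [n for n in history.names_in(release) if pattern in n]
    if count_only:
        return len(names)
    return sort_allele_names(names)


# ---------------------------------------------------------------------------
# allele translation


def translate_allele(
    name: str | AlleleName,
    from_release: str,
    to_release: str,
    history: AlleleHistory,
) -> AlleleName | None:
    """Translate one allele name between releases via its accession.

    Returns ``None`` when the accession has no entry in the target release
    (deleted there).  A truncated (1-2 field) name is expanded to every
    matching full name in the source release; each is translated and
    re-truncated, and the unique surviving name is returned.
    """
    allele = AlleleName.parse(name) if isinstance(name, str) else name
    key = allele.without_prefix().raw
    source_names = history.names_in(from_release)
    history._require(to_release)

    if key in source_names:
        translated = history.name_of(source_names[key], to_release)
        if translated is None:
            return None
        return replace(AlleleName.parse(translated), prefix=allele.prefix)

    k = allele.n_fields
    expansions = [
        full
        for full in source_names
        if AlleleName.parse(full).truncate(k).raw == key
    ]
    if not expansions:
        raise InvalidAlleleError(
            f"{allele.raw} is not a valid allele name in release {from_release}"
        )
    results = {
        history.name_of(source_names[full], to_release) for full in expansions
    }
    truncated = {
        AlleleName.parse(r).truncate(k).raw for r in results if r is not None
    }
    if not truncated:
        return None
    if len(truncated) > 1:
        raise AmbiguousTranslationError(
            f"{allele.raw} expands to names translating to "
            f"{sorted(truncated)} in {to_release}"
        )
    return replace(AlleleName.parse(truncated.pop()), prefix=allele.prefix)


# ---------------------------------------------------------------------------
# GL Strings

_GL_DELIMS = ("^", "|", "+", "~", "/")


@dataclass(frozen=True)
class GLString:
    """A parsed GL String; ``tree`` nests by delimiter precedence ^ | + ~ /."""

    raw: str

    @property
    def tree(self):
        return _split(self.raw, 0)

    @property
    def leaves(self) -> list[str]:
        return re.split(r"[\^|+~/]", self.raw)

    def render(self) -> str:
        return self.raw

    def validate(self) -> None:
        for leaf in self.leaves:
            AlleleName.parse(leaf)


def _split(text: str, level: int):
    if level == len(_GL_DELIMS):
        return text
    return [_split(part, level + 1) for part in text.split(_GL_DELIMS[level])]


def _join(tree, level: int) -> str:
    if level == len(_GL_DELIMS):
        return tree
    return _GL_DELIMS[level].join(_join(t, level + 1) for t in tree)


@dataclass(frozen=True)
class GLStringCode:
    """``namespace#version#glstring`` - a GL String pinned to a release."""

    namespace: str
    version: str
    glstring: GLString

    @classmethod
    def parse(cls, text: str) -> "GLStringCode":
        parts = text.split("#", 2)
        if len(parts) != 3:
            raise TranslationError(f"not a GL String Code: {text!r}")
        return cls(namespace=parts[0], version=parts[1], glstring=GLString(parts[2]))

    def render(self) -> str:
        return f"{self.namespace}#{self.version}#{self.glstring.render()}"


def translate_glstring(
    gl: GLString | GLStringCode | str,
    from_release: str,
    to_release: str,
    history: AlleleHistory,
    on_missing: OnMissing = "fail",
):
    """Translate every allele leaf of a GL String, preserving structure.

    ``on_missing`` controls leaves whose accession is absent from the
    target release: ``drop`` removes them (an ambiguity collapses to its
    surviving alleles; emptied branches are pruned), ``keep`` leaves the
    source-release name in place, ``fail`` raises naming the leaf.
    """
    if isinstance(gl, str):
        gl = GLStringCode.parse(gl) if "#" in gl else GLString(gl)
    if isinstance(gl, GLStringCode):
        inner = translate_glstring(
            gl.glstring, from_release, to_release, history, on_missing
        )
        return GLStringCode(namespace=gl.namespace, version=to_release, glstring=inner)

    def walk(node, level: int):
        if level == len(_GL_DELIMS):
            translated = translate_allele(node, from_release, to_release, history)
            if translated is None:
                if on_missing == "fail":
                    raise TranslationError(
                        f"allele {node} has no name in release {to_release}"
                    )
                if on_missing == "keep":
                    return node
                return None  # drop
            return translated.raw
        kept = [w for w in (walk(child, level + 1) for child in node) if w is not None]
        return kept or None

    tree = walk(gl.tree, 0)
    if tree is None:
        raise TranslationError(
            f"no allele in {gl.raw!r} survives translation to {to_release}"
        )
    return GLString(_join(tree, 0))


# ---------------------------------------------------------------------------
# whole-dataset translation

_LOCUS_COL = re.compile(r"^(.*)_(\d+)$")


def translate_dataset(
    table: pd.DataFrame,
    from_release: str,
    to_release: str,
    history: AlleleHistory,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translate a genotype table (``subject, <locus>_1, <locus>_2, ...``).

    Untranslatable cells (invalid in the source release, or deleted in the
    target) keep their original value and are counted in the report, which
    tallies translated / unchanged / untranslatable cells per locus.
    Blank cells are untyped and ignored.
    """
    cols = list(table.columns)
    if not cols or _LOCUS_COL.match(cols[0]):
        raise TranslationError(
            "genotype table must start with a subject column followed by "
            "<locus>_<n> allele columns"
        )
    locus_cols = [c for c in cols[1:] if _LOCUS_COL.match(c)]
    if not locus_cols:
        raise TranslationError("no <locus>_<n> allele columns found")
    out = table.copy()
    counts: dict[str, dict[str, int]] = {}
    for col in locus_cols:
        locus = _LOCUS_COL.match(col).group(1)
        tally = counts.setdefault(
            locus, {"translated": 0, "unchanged": 0, "untranslatable": 0}
        )
        new_col = []
        for cell in table[col]:
            if not isinstance(cell, str) or not cell.strip():
                new_col.append(cell)
                continue
            cell = cell.strip()
            try:
                translated = translate_allele(cell, from_release, to_release, history)
            except (AlleleNameError, TranslationError):
                translated = None
            if translated is None:
                tally["untranslatable"] += 1
                new_col.append(cell)
            elif translated.raw == cell:
                tally["unchanged"] += 1
                new_col.append(cell)
            else:
                tally["translated"] += 1
                new_col.append(translated.raw)
        out[col] = new_col
    report = pd.DataFrame.from_dict(counts, orient="index").rename_axis("locus")
    return out, report
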