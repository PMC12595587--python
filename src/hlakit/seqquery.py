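"""Position and motif queries over alignment tables.

Everything here operates on the expanded alleles-x-positions matrices from
:mod:`hlakit.imgt_io`: extracting the residues an allele carries at chosen
positions, finding every allele that carries a residue motif, and
summarising per-position variant distributions.  ``*`` (unknown sequence)
never matches a query and is excluded from denominators; ``.`` (indel) is
an ordinary matchable symbol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .imgt_io import AlignmentTable, _NUC_SYMBOLS, _PROT_SYMBOLS
from .names import AlleleName, MotifSpec, sort_allele_names


class QueryError(ValueError):
    pass


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving a possibly-truncated allele name in a table."""

    found: bool
    canonical: str | None = None
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


def validate_allele(name: str | AlleleName, table: AlignmentTable) -> Resolution:
    """Resolve a (possibly truncated) allele name against alignment rows.

    A truncated name matching several full names resolves deterministically
    to the lexicographically first one; the ambiguity is flagged in the
    returned :class:`Resolution` and warned about, never silent.
    """
    allele = AlleleName.parse(name) if isinstance(name, str) else name
    key = allele.without_prefix().raw
    if key in table.rows:
        return Resolution(found=True, canonical=key)
    k = allele.n_fields
    candidates = tuple(
        sort_allele_names(
            n for n in table.rows if AlleleName.parse(n).truncate(k).raw == key
        )
    )
    if not candidates:
        return Resolution(found=False)
    if len(candidates) > 1:
        warnings.warn(
            f"{key} is ambiguous in the {table.locus} {table.align_type} "
            f"alignment ({len(candidates)} expansions); using {candidates[0]}",
            stacklevel=2,
        )
    return Resolution(
        found=True,
        canonical=candidates[0],
        ambiguous=len(candidates) > 1,
        candidates=candidates,
    )


def alignment_search(
    table: AlignmentTable,
    allele: str | AlleleName,
    positions: Sequence[str | int],
) -> str:
    """Residues of one allele at chosen positions, as ``"25Q~38V~..."``."""
    res = validate_allele(allele, table)
    if not res.found:
        raise QueryError(
            f"allele {allele} not in the {table.locus} {table.align_type} alignment"
        )
    symbols = table.symbols_at(res.canonical, positions)
    return "~".join(f"{p}{s}" for p, s in zip(positions, symbols))


def query_positions(
    table: AlignmentTable, positions: Sequence[str | int]
) -> pd.DataFrame:
    """Residue counts over all alleles at each position.

    Returns a long-format frame (position, residue, count) excluding ``*``;
    the per-position denominator (alleles with known sequence) is in
    :func:`position_denominator` / :func:`position_fraction`.
    """
    records = []
    for pos in positions:
        j = table.col_index(pos)
        counts: dict[str, int] = {}
        for row in table.rows.values():
            sym = row[j]
            if sym != "*":
                counts[sym] = counts.get(sym, 0) + 1
        for sym in sorted(counts):
            records.append({"position": str(pos), "residue": sym, "count": counts[sym]})
    return pd.DataFrame(records, columns=["position", "residue", "count"])


def position_denominator(table: AlignmentTable, position: str | int) -> int:
    j = table.col_index(position)
    return sum(1 for row in table.rows.values() if row[j] != "*")


def position_fraction(
    table: AlignmentTable, position: str | int, residues: Sequence[str]
) -> float:
    """Fraction of sequenced alleles carrying one of ``residues`` there."""
    j = table.col_index(position)
    n = hits = 0
    for row in table.rows.values():
        if row[j] != "*":
            n += 1
            if row[j] in residues:
                hits += 1
    return hits / n if n else float("nan")


def motif_match(
    motif: MotifSpec | str,
    table: AlignmentTable,
    truncate_to: int | None = None,
) -> list[str]:
    """All alleles whose expanded row carries every motif term.

    With ``truncate_to`` the hits are truncated to that many name fields
    (expression suffixes preserved), deduplicated and sorted - the form in
    which two-field population frequency data are reported.
    """
    spec = MotifSpec.parse(motif) if isinstance(motif, str) else motif
    alphabet = _PROT_SYMBOLS if table.align_type == "prot" else _NUC_SYMBOLS
    for _, residue in spec.terms:
        if residue == "*" or residue not in alphabet:
            raise QueryError(f"residue {residue!r} not in the alignment alphabet")
    cols = [table.col_index(p) for p in spec.positions]
    hits = []
    for name, row in table.rows.items():
        if all(row[j] == residue for j, (_, residue) in zip(cols, spec.terms)):
            hits.append(name)
    if truncate_to is not None:
        hits = {AlleleName.parse(n).truncate(truncate_to).raw for n in hits}
    return sort_allele_names(hits)


def custom_align(
    requests: Sequence[tuple[str, str, Sequence[str | int]]],
    alleles: Sequence[str | AlleleName],
    tables: Mapping[tuple[str, str], AlignmentTable],
) -> pd.DataFrame:
    """A rectangular multi-locus mini-alignment.

    ``requests`` pairs each locus with an alignment type and position list;
    each allele is matched to the request for its own locus.  Rows are
    alleles, columns positions (ragged requests padded with ``*``), cells
    ``"<position><residue>"`` terms.
    """
    by_locus: dict[str, tuple[str, Sequence[str | int]]] = {}
    for locus, align_type, positions in requests:
        if (locus, align_type) not in tables:
            raise QueryError(f"no {align_type} alignment available for {locus}")
        by_locus[locus] = (align_type, positions)
    width = max(len(p) for _, p in by_locus.values())
    rows = {}
    for allele in alleles:
        parsed = AlleleName.parse(allele) if isinstance(allele, str) else allele
        if parsed.locus not in by_locus:
            raise QueryError(f"no request for locus {parsed.locus}")
        align_type, positions = by_locus[parsed.locus]
        table = tables[(parsed.locus, align_type)]
        terms = alignment_search(table, parsed, positions).split("~")
        rows[parsed.raw] = terms + ["*"] * (width - len(terms))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"pos_{i + 1}" for i in range(width)]
    )
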