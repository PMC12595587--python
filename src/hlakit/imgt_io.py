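"""Readers and writers for IPD-IMGT/HLA repository resources.

The IMGT alignment dialect presents a multiple sequence alignment in blocks
of 50-100 positions: within a block, one line per allele, the first sequence
of the first block being the reference.  ``-`` means identity to the
reference, ``.`` an indel, ``*`` unknown/unsequenced sequence, ``X`` a stop
codon (protein alignments), and ``|`` characters embedded in sequence lines
mark gene-feature boundaries.  This module flattens those blocks into
:class:`AlignmentTable` objects - one allele per row, one aligned position
per column - which every downstream query consumes.

Also here: the allele-list history (accession x release -> allele name),
the packaged gene-metadata table (expression status, class, chromosomal map
order) and a cached fetcher for per-release files on the ANHIG/IMGTHLA
repository, where each git branch corresponds to one database release.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .names import (
    AlleleName,
    AlleleNameError,
    format_label,
    label_key,
    next_position,
)

ALIGN_TYPES = ("prot", "codon", "nuc", "gen")

#: symbols legal in an expanded alignment row
_PROT_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWYX.*")
_NUC_SYMBOLS = frozenset("ACGTRYSWKMBDHVN.*")

RAW_BASE_URL = "https://raw.githubusercontent.com/ANHIG/IMGTHLA"
API_BASE_URL = "https://api.github.com/repos/ANHIG/IMGTHLA/contents"


class ImgtParseError(ValueError):
    """Raised when an IMGT-dialect or history file cannot be parsed."""


class FetchError(RuntimeError):
    """Base class for release-file retrieval failures."""


class UnknownReleaseError(FetchError):
    pass


class UnknownFileError(FetchError):
    pass


class OfflineError(FetchError):
    """No network and no cached copy; callers should fall back to fixtures."""


# ---------------------------------------------------------------------------
# AlignmentTable


@dataclass(frozen=True)
class Boundary:
    """A gene-feature boundary between two alignment columns.

    ``col_index`` is the 0-based index of the first column *after* the
    boundary; the boundary therefore sits between columns ``col_index - 1``
    and ``col_index``.
    """

    before: str
    after: str
    col_index: int


@dataclass
class AlignmentTable:
    """One locus, one alignment type, alleles x aligned positions."""

    locus: str
    align_type: str
    version: str
    reference_allele: str
    column_labels: list[str]
    rows: dict[str, list[str]]
    boundary_columns: list[Boundary] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.column_labels)

    @property
    def allele_names(self) -> list[str]:
        return list(self.rows)

    def col_index(self, label: str | int) -> int:
        label = str(label)
        try:
            return self.column_labels.index(label)
        except ValueError:
            lo, hi = self.column_labels[0], self.column_labels[-1]
            raise KeyError(
                f"position {label} not in {self.locus} {self.align_type} "
                f"alignment (valid range {lo}..{hi})"
            ) from None

    def symbols_at(self, allele: str, labels: Sequence[str | int]) -> list[str]:
        row = self.rows[allele]
        return [row[self.col_index(lab)] for lab in labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            self.rows, orient="index", columns=self.column_labels
        )

    def feature_intervals(self) -> list[tuple[str, int, int]]:
        """(feature_label, first_col, last_col) between consecutive boundaries."""
        if not self.boundary_columns:
            return [("E.1" if self.align_type != "gen" else "gene", 0, self.n_columns - 1)]
        out = []
        start = 0
        for b in self.boundary_columns:
            out.append((b.before, start, b.col_index - 1))
            start = b.col_index
        out.append((self.boundary_columns[-1].after, start, self.n_columns - 1))
        return out

    def validate(self) -> None:
        n = self.n_columns
        if len(set(self.column_labels)) != n:
            raise ImgtParseError("duplicate column labels")
        keys = [label_key(c) for c in self.column_labels]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ImgtParseError("column labels not strictly ordered")
        alphabet = _PROT_SYMBOLS if self.align_type == "prot" else _NUC_SYMBOLS
        for name, row in self.rows.items():
            if len(row) != n:
                raise ImgtParseError(
                    f"row {name} has {len(row)} symbols, expected {n}"
                )
            if self.align_type != "codon" and not set(row) <= alphabet:
                bad = sorted(set(row) - alphabet)
                raise ImgtParseError(f"row {name} has illegal symbols {bad}")
        ref = self.rows[self.reference_allele]
        if "-" in ref:
            raise ImgtParseError("reference row contains identity dashes")
        idx = [b.col_index for b in self.boundary_columns]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ImgtParseError("boundary columns not strictly increasing")


# ---------------------------------------------------------------------------
# parsing the block dialect

_HEADER_WORDS = {"Prot", "cDNA", "gDNA", "AA"}
_SEQLINE_RE = re.compile(r"^\s*([A-Z][A-Za-z0-9]*\*[\d:]+[NLSCAQ]?)\s+(\S.*)$")
_VERSION_RE = re.compile(r"version[:\s]+(?:IPD-IMGT/HLA\s+)?([\d.]+)", re.I)


def _boundary_feature_labels(n_boundaries: int, align_type: str) -> list[tuple[str, str]]:
    """Assign (before, after) feature labels to n ordered boundary markers.

    Genomic alignments with an even marker count follow the standard layout
    5'UTR | Exon 1 | Intron 1 | ... | last Exon | 3'UTR.  Protein and cDNA
    alignments only mark exon/exon junctions.  Anything else gets neutral
    ``F.n`` labels (gene fragments with atypical structure keep their
    boundaries; naming them is the atlas/classifier's job).
    """
    if align_type == "gen" and n_boundaries >= 2 and n_boundaries % 2 == 0:
        n_exons = n_boundaries // 2
        feats = ["U.5"]
        for i in range(1, n_exons):
            feats += [f"E.{i}", f"I.{i}"]
        feats += [f"E.{n_exons}", "U.3"]
        return list(zip(feats[:-1], feats[1:]))
    if align_type in ("nuc", "codon", "prot"):
        return [(f"E.{i}", f"E.{i + 1}") for i in range(1, n_boundaries + 1)]
    feats = [f"F.{i}" for i in range(1, n_boundaries + 2)]
    return list(zip(feats[:-1], feats[1:]))


def parse_alignment(text: str, align_type: str, locus: str | None = None) -> AlignmentTable:
    """Parse IMGT-dialect block alignment text into an :class:`AlignmentTable`.

    Identity dashes are expanded to the reference symbol; alleles entering
    only in later blocks are left-padded with ``*`` and rows ending early
    are right-padded with ``*``.  Boundary ``|`` markers are stripped into
    :class:`Boundary` records.
    """
    if align_type not in ALIGN_TYPES:
        raise ValueError(f"align_type must be one of {ALIGN_TYPES}")
    version = ""
    start_label: int | None = None
    # per-allele list of (block_index, symbols); boundaries as global offsets
    blocks: list[dict[str, list[str]]] = []
    block_boundaries: list[set[int]] = []
    block_index = -1
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = _VERSION_RE.search(stripped)
            if m:
                version = m.group(1)
            continue
        first = stripped.split()[0]
        if first in _HEADER_WORDS:
            if first == "AA":  # "AA codon" sub-header of nucleotide files
                continue
            block_index += 1
            blocks.append({})
            block_boundaries.append(set())
            if start_label is None:
                nums = re.findall(r"-?\d+", stripped)
                if not nums:
                    raise ImgtParseError(
                        f"malformed position-label line in block {block_index + 1}"
                        f" (line {lineno}): {stripped!r}"
                    )
                start_label = int(nums[0])
            continue
        if set(stripped) <= {"|"}:
            continue  # anchor marker line under the position labels
        m = _SEQLINE_RE.match(line)
        if m is None:
            continue  # footers and free-text annotations
        if block_index < 0:
            raise ImgtParseError(
                f"sequence line before any position-label line (line {lineno})"
            )
        name, body = m.group(1), m.group(2)
        if name in blocks[block_index]:
            raise ImgtParseError(
                f"duplicate allele {name} in block {block_index + 1}"
            )
        symbols: list[str] = []
        for ch in body:
            if ch == " ":
                continue
            if ch == "|":
                block_boundaries[block_index].add(len(symbols))
            else:
                symbols.append(ch)
        blocks[block_index][name] = symbols
    if not blocks or not blocks[0]:
        raise ImgtParseError("no alignment blocks found")
    if start_label is None:
        raise ImgtParseError("no position-label line found")

    reference = next(iter(blocks[0]))
    # block widths from the reference (falling back to each block's longest row)
    widths = []
    for i, blk in enumerate(blocks):
        widths.append(len(blk[reference]) if reference in blk else max(map(len, blk.values())))
    offsets = [0]
    for w in widths:
        offsets.append(offsets[-1] + w)
    n_columns = offsets[-1]

    order: list[str] = []
    rows: dict[str, list[str]] = {}
    for i, blk in enumerate(blocks):
        for name, symbols in blk.items():
            if len(symbols) > widths[i]:
                raise ImgtParseError(
                    f"allele {name} has {len(symbols)} symbols in block "
                    f"{i + 1}, expected at most {widths[i]}"
                )
            if name not in rows:
                order.append(name)
                rows[name] = ["*"] * offsets[i]  # late entry: left-pad unknown
            elif len(rows[name]) < offsets[i]:
                rows[name] += ["*"] * (offsets[i] - len(rows[name]))
            rows[name] += symbols + ["*"] * (widths[i] - len(symbols))
    for name in order:
        rows[name] += ["*"] * (n_columns - len(rows[name]))

    ref_row = rows[reference]
    for name in order[1:]:
        row = rows[name]
        for j, sym in enumerate(row):
            if sym == "-":
                row[j] = ref_row[j]

    boundary_cols = sorted(
        {offsets[i] + off for i, offs in enumerate(block_boundaries) for off in offs}
    )
    labels_pairs = _boundary_feature_labels(len(boundary_cols), align_type)
    boundaries = [
        Boundary(before, after, col)
        for (before, after), col in zip(labels_pairs, boundary_cols)
    ]

    # synthesize position labels by walking the reference row: columns where
    # the reference holds "." are insertion columns labelled n.k
    column_labels: list[str] = []
    pos: int | None = None
    sub = 0
    for sym in ref_row:
        if sym == ".":
            sub += 1
            column_labels.append(format_label(pos if pos is not None else 0, sub))
        else:
            pos = start_label if pos is None else next_position(pos)
            sub = 0
            column_labels.append(format_label(pos))

    if locus is None:
        locus = AlleleName.parse(reference).locus
    table = AlignmentTable(
        locus=locus,
        align_type=align_type,
        version=version,
        reference_allele=reference,
        column_labels=column_labels,
        rows={name: rows[name] for name in order},
        boundary_columns=boundaries,
    )
    table.validate()
    return table


def write_alignment(table: AlignmentTable, block_width: int = 60) -> str:
    """Serialize back to the block dialect; re-parsing yields an equal table.

    Alleles entering late / ending early are omitted from their all-unknown
    leading / trailing blocks, reproducing the upstream convention.
    """
    word = {"prot": "Prot", "nuc": "cDNA", "codon": "cDNA", "gen": "gDNA"}[table.align_type]
    ref = table.rows[table.reference_allele]
    names = table.allele_names
    for n in names:
        if set(table.rows[n]) == {"*"}:
            raise ImgtParseError(f"row {n} is entirely unknown; cannot serialize")
    name_w = max(len(n) for n in names) + 4
    bcols = [b.col_index for b in table.boundary_columns]
    first_nonstar = {
        n: next(i for i, s in enumerate(table.rows[n]) if s != "*") for n in names
    }
    last_nonstar = {
        n: max(i for i, s in enumerate(table.rows[n]) if s != "*") for n in names
    }

    lines = [
        f"# file: {table.locus}_{table.align_type}.txt",
        f"# version: IPD-IMGT/HLA {table.version}" if table.version else "# version: IPD-IMGT/HLA",
        "",
    ]
    for start in range(0, table.n_columns, block_width):
        end = min(start + block_width, table.n_columns)
        # first integer anchor within the block
        anchor = next(
            (lab for lab in table.column_labels[start:end] if "." not in lab),
            table.column_labels[start],
        )
        lines.append(f" {word}{' ' * (name_w - len(word) - 1)}{anchor}")
        for n in names:
            if first_nonstar[n] >= end or last_nonstar[n] < start:
                continue  # not yet entered / already ended: omit, reparse pads *
            row = table.rows[n]
            out = []
            for j in range(start, end):
                if j in bcols:
                    out.append("|")
                if j > start and (j - start) % 10 == 0:
                    out.append(" ")
                sym = row[j]
                if n != table.reference_allele and sym == ref[j] and sym != "*":
                    sym = "-"
                out.append(sym)
            if end in bcols and end == table.n_columns:
                out.append("|")
            lines.append(f" {n:<{name_w - 1}}{''.join(out)}")
        lines.append("")
    return "\n".join(lines) + "\n"


def write_alignment_tsv(table: AlignmentTable, path: str | Path) -> None:
    """Write the expanded alleles-x-positions matrix as TSV."""
    table.to_frame().to_csv(path, sep="\t", index_label="allele")


# ---------------------------------------------------------------------------
# codon tables

LEADER_CODONS = {
    # signal-peptide lengths (codons) for loci whose worked positions matter;
    # derived at run time from protein alignments when available
    "G": 24,
}


def derive_codon_table(nuc: AlignmentTable) -> AlignmentTable:
    """Group a coding-nucleotide alignment into codons (3 nt per column).

    Codon *i* comprises cDNA positions 3i-2..3i counted from the start of
    Exon 1; insertion columns are appended to the codon of their anchor
    position.  Cells are 3+ character strings (e.g. ``"ATG"``).
    """
    if nuc.align_type != "nuc":
        raise ValueError("codon tables derive from nuc alignments")
    codon_of: dict[int, list[int]] = {}
    codon_order: list[int] = []
    for j, lab in enumerate(nuc.column_labels):
        anchor = label_key(lab)[0]
        codon = max(1, math.ceil(anchor / 3)) if anchor > 0 else anchor  # pre-start kept raw
        if codon not in codon_of:
            codon_of[codon] = []
            codon_order.append(codon)
        codon_of[codon].append(j)
    rows = {
        name: ["".join(row[j] for j in cols) for c in codon_order for cols in [codon_of[c]]]
        for name, row in nuc.rows.items()
    }
    # boundaries move to the codon containing the first nucleotide after them
    boundaries = []
    col_to_codonidx = {}
    for ci, c in enumerate(codon_order):
        for j in codon_of[c]:
            col_to_codonidx[j] = ci
    for b in nuc.boundary_columns:
        if b.col_index in col_to_codonidx:
            boundaries.append(Boundary(b.before, b.after, col_to_codonidx[b.col_index]))
    dedup: list[Boundary] = []
    for b in boundaries:
        if not dedup or b.col_index > dedup[-1].col_index:
            dedup.append(b)
    return AlignmentTable(
        locus=nuc.locus,
        align_type="codon",
        version=nuc.version,
        reference_allele=nuc.reference_allele,
        column_labels=[str(c) for c in codon_order],
        rows=rows,
        boundary_columns=dedup,
    )


# ---------------------------------------------------------------------------
# allele-list history


@dataclass
class AlleleHistory:
    """Accession-keyed map of allele names across database releases."""

    version_list: list[str]
    table: dict[str, dict[str, str]]
    source_version: str

    def name_of(self, accession: str, release: str) -> str | None:
        return self.table.get(accession, {}).get(release)

    def names_in(self, release: str) -> dict[str, str]:
        """allele name -> accession for one release."""
        self._require(release)
        return {
            name: acc
            for acc, entry in self.table.items()
            if (name := entry.get(release)) is not None
        }

    def accession_of(self, name: str, release: str) -> str | None:
        return self.names_in(release).get(name)

    def _require(self, release: str) -> None:
        if release not in self.version_list:
            raise KeyError(
                f"unknown release {release!r}; available: {', '.join(self.version_list)}"
            )


def release_from_tag(tag: str) -> str:
    """``"3590"`` -> ``"3.59.0"``; already-dotted strings pass through."""
    tag = tag.strip()
    if "." in tag:
        return tag
    if not (tag.isdigit() and len(tag) == 4):
        raise ImgtParseError(f"unparseable release header {tag!r}")
    return f"{tag[0]}.{tag[1:3]}.{tag[3]}"


def release_to_branch(release: str) -> str:
    """``"3.59.0"`` -> repository branch ``"3590"``; ``"Latest"`` verbatim."""
    if release == "Latest":
        return release
    parts = release.split(".")
    if len(parts) != 3 or not all(p.isdigit() for p in parts):
        raise ValueError(f"unrecognised release string {release!r}")
    major, minor, patch = parts
    return f"{major}{minor.zfill(2)}{patch}"


def parse_allele_history(text: str) -> AlleleHistory:
    """Parse ``Allelelist_history.txt`` (CSV, one column per release)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ImgtParseError("empty allele-list history")
    header = [c.strip() for c in lines[0].split(",")]
    if header[0].upper() not in ("HLA_ID", "ACCESSION", "ID"):
        raise ImgtParseError(
            f"missing accession column (first header cell {header[0]!r})"
        )
    releases = [release_from_tag(tag) for tag in header[1:]]
    table: dict[str, dict[str, str]] = {}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        acc = cells[0]
        entry: dict[str, str] = {}
        for rel, cell in zip(releases, cells[1:]):
            if cell:
                AlleleName.parse(cell)  # every recorded name must parse
                entry[rel] = cell
        table[acc] = entry
    return AlleleHistory(
        version_list=releases, table=table, source_version=releases[0] if releases else ""
    )


def write_allele_history(history: AlleleHistory) -> str:
    tags = [release_to_branch(r) for r in history.version_list]
    lines = ["HLA_ID," + ",".join(tags)]
    for acc, entry in history.table.items():
        lines.append(
            acc + "," + ",".join(entry.get(r, "") for r in history.version_list)
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# gene metadata (packaged table replacing the hla.alleles.org HTML scrape)


@dataclass(frozen=True)
class GeneMetadata:
    gene: str
    status: str  # expressed | pseudogene | gene_fragment
    hla_class: str  # I | II | other
    map_index: int
    merged_map_group: str | None = None
    classical: bool = False


def load_gene_metadata(path: str | Path | None = None) -> dict[str, GeneMetadata]:
    if path is None:
        source = importlib.resources.files("hlakit.data") / "gene_metadata.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    df = pd.read_csv(
        __import__("io").StringIO(text), sep="\t", dtype=str, keep_default_na=False
    )
    out: dict[str, GeneMetadata] = {}
    for rec in df.itertuples(index=False):
        out[rec.gene] = GeneMetadata(
            gene=rec.gene,
            status=rec.status,
            hla_class=rec.hla_class,
            map_index=int(rec.map_index),
            merged_map_group=rec.merged_map_group or None,
            classical=rec.classical == "1",
        )
    return out


# ---------------------------------------------------------------------------
# release-file retrieval with mandatory cache


def fetch_release_file(
    release: str,
    path: str,
    cache_dir: str | Path,
    timeout: float = 15.0,
) -> str:
    """Fetch a file from the branch matching ``release``, caching on disk.

    The cache is keyed by (release branch, path); once a file is cached the
    network is never touched again for it.  Offline with no cached copy
    raises :class:`OfflineError` telling the caller to use fixture mode.
    """
    branch = release_to_branch(release)
    cache_file = Path(cache_dir) / branch / path
    if cache_file.exists():
        return cache_file.read_text()
    url = f"{RAW_BASE_URL}/{branch}/{path}"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            # distinguish a missing branch (unknown release) from a missing file
            probe = f"{RAW_BASE_URL}/{branch}/README.md"
            try:
                urllib.request.urlopen(probe, timeout=timeout).close()
            except urllib.error.HTTPError:
                raise UnknownReleaseError(
                    f"release {release} (branch {branch}) not found upstream"
                ) from exc
            except urllib.error.URLError as net:
                raise OfflineError(_offline_msg(release, path)) from net
            raise UnknownFileError(f"no file {path!r} in release {release}") from exc
        raise FetchError(f"HTTP {exc.code} fetching {url}") from exc
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise OfflineError(_offline_msg(release, path)) from exc
    cache_file.parent.mkdir(parents=True, exist_ok=True)
    cache_file.write_text(text)
    return text


def _offline_msg(release: str, path: str) -> str:
    return (
        f"cannot reach the ANHIG/IMGTHLA repository and {path!r} for release "
        f"{release} is not cached; populate the cache directory or use "
        "hlakit.fixtures to generate an offline corpus"
    )


_INV_RE = re.compile(r"^([A-Za-z0-9]+)_(prot|nuc|gen)\.txt$")


def inventory_from_filenames(
    filenames: Iterable[str],
    metadata: Mapping[str, GeneMetadata] | None = None,
) -> dict[str, set[str]]:
    """Map locus -> available alignment types from alignment file names.

    ``codon`` availability is implied by ``nuc`` for expressed genes.
    """
    if metadata is None:
        metadata = load_gene_metadata()
    inv: dict[str, set[str]] = {}
    for fn in filenames:
        m = _INV_RE.match(Path(fn).name)
        if m:
            inv.setdefault(m.group(1), set()).add(m.group(2))
    for locus, types in inv.items():
        meta = metadata.get(locus)
        if "nuc" in types and meta is not None and meta.status == "expressed":
            types.add("codon")
    return inv


def list_alignment_inventory(
    release: str | None = None,
    directory: str | Path | None = None,
    cache_dir: str | Path | None = None,
    metadata: Mapping[str, GeneMetadata] | None = None,
    timeout: float = 15.0,
) -> dict[str, set[str]]:
    """List available (locus, alignment type) pairs for a release or directory."""
    if directory is not None:
        names = [p.name for p in Path(directory).iterdir() if p.is_file()]
        return inventory_from_filenames(names, metadata)
    if release is None:
        raise ValueError("need a release or a directory")
    branch = release_to_branch(release)
    listing_cache = None
    if cache_dir is not None:
        listing_cache = Path(cache_dir) / branch / "_alignments_listing.json"
        if listing_cache.exists():
            names = json.loads(listing_cache.read_text())
            return inventory_from_filenames(names, metadata)
    url = f"{API_BASE_URL}/alignments?ref={branch}"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            entries = json.loads(resp.read().decode())
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            raise UnknownReleaseError(f"release {release} not found upstream") from exc
        raise FetchError(f"HTTP {exc.code} listing alignments for {release}") from exc
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise OfflineError(_offline_msg(release, "alignments/")) from exc
    names = [e["name"] for e in entries]
    if listing_cache is not None:
        listing_cache.parent.mkdir(parents=True, exist_ok=True)
        listing_cache.write_text(json.dumps(names))
    return inventory_from_filenames(names, metadata)
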