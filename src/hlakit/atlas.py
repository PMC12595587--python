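"""Gene-feature geography of HLA loci.

Three related resources are built here from parsed alignments:

* an *atlas*: for each locus and alignment type, the position of every
  gene-feature boundary, flanked by the last column label before and the
  first after it (and, for coding-nucleotide alignments, the codon the
  boundary falls in);
* *feature sets* for pseudogenes and gene fragments, whose structure need
  not match an expressed gene.  Features that align cleanly to a reference
  feature keep the standard exon/intron/UTR labels; everything else is
  classified as hybrid (H), join (J), novel (N) or segment (S), numbered by
  order of appearance 5' to 3';
* a *gazetteer* organising the curated genes into named categories
  (alignment availability, expression status, class, chromosomal map order,
  ...).

Class I fragments are conventionally compared against the HLA-C genomic
reference (the longest class I gene body); the DP pseudogenes against
DPA1/DPB1.  The classifier itself is agnostic: it consumes an explicit
column pairing between fragment and reference alignments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .imgt_io import AlignmentTable, GeneMetadata, label_key

NONSTANDARD_CLASSES = ("H", "J", "N", "S")
STANDARD_PREFIXES = ("U", "E", "I")

#: references used for genomic comparison of non-expressed loci
FRAGMENT_REFERENCES = {
    "DPA2": "DPA1",
    "DPB2": "DPB1",
    # every class I pseudogene / fragment aligns against HLA-C
    **{g: "C" for g in "HJKLNPRSTUVWY"},
}

GAZETTEER_CATEGORIES = (
    "all",
    "align",
    "gen",
    "nuc",
    "prot",
    "codon",
    "nogen",
    "nonuc",
    "noprot",
    "expressed",
    "pseudogene",
    "gene_fragment",
    "classI",
    "classII",
    "classical",
    "nonclassical",
    "hla_loci",
    "nonhla_loci",
    "map",
)

NON_HLA_GENES = frozenset({"HFE", "MICA", "MICB", "TAP1", "TAP2"})


class AtlasError(ValueError):
    pass


@dataclass(frozen=True)
class BoundaryRecord:
    left_feature: str
    right_feature: str
    before_label: str
    after_label: str
    codon: int | None = None


@dataclass
class Atlas:
    """Per-locus, per-alignment-type gene-feature boundary positions."""

    entries: dict[str, dict[str, list[BoundaryRecord]]] = field(default_factory=dict)
    version: str = ""

    def boundaries(self, locus: str, align_type: str) -> list[BoundaryRecord]:
        return self.entries[locus][align_type]

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "entries": {
                locus: {
                    at: [vars(b) for b in recs] for at, recs in per.items()
                }
                for locus, per in self.entries.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Atlas":
        payload = json.loads(text)
        entries = {
            locus: {
                at: [BoundaryRecord(**b) for b in recs] for at, recs in per.items()
            }
            for locus, per in payload["entries"].items()
        }
        return cls(entries=entries, version=payload["version"])


def leader_codons_from_prot(prot: AlignmentTable) -> int:
    """Signal-peptide length = count of negative protein positions."""
    return sum(1 for lab in prot.column_labels if "." not in lab and int(lab) < 0)


def build_atlas(
    tables: Iterable[AlignmentTable],
    leader_codons: int | None = None,
) -> Atlas:
    """Locate every gene-feature boundary in each alignment.

    For coding-nucleotide alignments the codon of a boundary is the codon
    containing the first nucleotide after it, numbered on the mature
    protein: ``ceil(cDNA position / 3) - leader_codons``.  The leader length
    is taken from the locus' protein alignment when one is supplied.
    """
    by_locus: dict[str, dict[str, AlignmentTable]] = {}
    for t in tables:
        by_locus.setdefault(t.locus, {})[t.align_type] = t
    atlas = Atlas()
    for locus, per_type in by_locus.items():
        leaders = leader_codons
        if leaders is None and "prot" in per_type:
            leaders = leader_codons_from_prot(per_type["prot"])
        atlas.entries[locus] = {}
        for at, table in per_type.items():
            recs = []
            for b in table.boundary_columns:
                if b.col_index <= 0 or b.col_index >= table.n_columns:
                    raise AtlasError(
                        f"{locus} {at}: boundary marker at alignment edge "
                        f"(column {b.col_index})"
                    )
                codon = None
                if at == "nuc":
                    # a boundary on a codon multiple belongs to the completed
                    # codon before it; a mid-codon boundary to the codon of
                    # the first nucleotide after it.  Numbering is on the
                    # mature protein (leader codons subtracted).
                    before = label_key(table.column_labels[b.col_index - 1])[0]
                    after = label_key(table.column_labels[b.col_index])[0]
                    raw = before // 3 if before % 3 == 0 else math.ceil(after / 3)
                    codon = raw - (leaders or 0)
                recs.append(
                    BoundaryRecord(
                        left_feature=b.before,
                        right_feature=b.after,
                        before_label=table.column_labels[b.col_index - 1],
                        after_label=table.column_labels[b.col_index],
                        codon=codon,
                    )
                )
            atlas.entries[locus][at] = recs
        if not atlas.version:
            atlas.version = next(iter(per_type.values())).version
    return atlas


# ---------------------------------------------------------------------------
# gene-body length


def gene_body_length(gen_table: AlignmentTable, allele: str) -> int:
    """Length in nucleotides of the gene body (all exons and introns).

    Counts non-indel symbols in the allele's genomic row between the
    5'UTR/Exon-1 boundary and the last-exon/3'UTR boundary.
    """
    if allele not in gen_table.rows:
        raise KeyError(f"allele {allele} not in {gen_table.locus} gen alignment")
    start = end = None
    for b in gen_table.boundary_columns:
        if b.before == "U.5":
            start = b.col_index
        if b.after == "U.3":
            end = b.col_index
    if start is None or end is None:
        raise AtlasError(
            f"{gen_table.locus} gen alignment lacks UTR boundaries; "
            "cannot delimit the gene body"
        )
    row = gen_table.rows[allele]
    return sum(1 for sym in row[start:end] if sym != ".")


# ---------------------------------------------------------------------------
# fragment / pseudogene feature classification


@dataclass
class FeatureSet:
    """Ordered feature labels of a pseudogene or gene fragment."""

    gene: str
    reference_gene: str
    features: list[str]
    annotation: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSet":
        return cls(**json.loads(text))


def identity_pairing(fragment: AlignmentTable, reference: AlignmentTable) -> list[int | None]:
    """Column pairing when fragment and reference share alignment coordinates."""
    if fragment.n_columns != reference.n_columns:
        raise AtlasError("identity pairing needs equal column counts")
    return list(range(fragment.n_columns))


def pairing_from_sequences(
    fragment_gen: AlignmentTable,
    reference_gen: AlignmentTable,
    min_run: int = 30,
    min_identity: float = 0.7,
) -> list[int | None]:
    """Estimate a column pairing by aligning the two reference sequences.

    A semi-global edit-distance alignment (edlib) places the fragment inside
    the reference; fragment positions are called *aligned* only within runs
    of at least ``min_run`` aligned columns whose identity reaches
    ``min_identity`` - shorter or noisier stretches are treated as novel
    sequence.  This is the pluggable fallback for fragments that do not
    share multiple-alignment coordinates with their reference; a curated
    pairing, when available, should be preferred.
    """
    import edlib

    def ungapped(table: AlignmentTable) -> tuple[str, list[int]]:
        row = table.rows[table.reference_allele]
        cols = [j for j, s in enumerate(row) if s not in ".*"]
        return "".join(row[j] for j in cols), cols

    frag_seq, frag_cols = ungapped(fragment_gen)
    ref_seq, ref_cols = ungapped(reference_gen)
    result = edlib.align(frag_seq, ref_seq, mode="HW", task="path")
    pairs = edlib.getNiceAlignment(result, frag_seq, ref_seq)
    qa, ta = pairs["query_aligned"], pairs["target_aligned"]
    start = result["locations"][0][0]
    qi, ti = 0, start
    raw: list[tuple[int, int, bool]] = []  # (frag_idx, ref_idx, is_match)
    for q, t in zip(qa, ta):
        if q != "-" and t != "-":
            raw.append((qi, ti, q == t))
            qi += 1
            ti += 1
        elif q != "-":
            qi += 1
        else:
            ti += 1
    pairing: list[int | None] = [None] * fragment_gen.n_columns
    # accept only long, high-identity runs of consecutive aligned positions
    run: list[tuple[int, int, bool]] = []

    def flush() -> None:
        if len(run) >= min_run and sum(m for *_x, m in run) / len(run) >= min_identity:
            for fi, ri, _ in run:
                pairing[frag_cols[fi]] = ref_cols[ri]

    prev = None
    for fi, ri, m in raw:
        if prev is not None and (fi != prev[0] + 1 or ri != prev[1] + 1):
            flush()
            run = []
        run.append((fi, ri, m))
        prev = (fi, ri)
    flush()
    return pairing


def classify_fragment_features(
    fragment_gen: AlignmentTable,
    reference_gen: AlignmentTable,
    pairing: Sequence[int | None],
) -> FeatureSet:
    """Name a fragment's features by comparison with a genomic reference.

    ``pairing[j]`` is the reference column the fragment's column *j* aligns
    to, or ``None`` where the fragment sequence has no reference
    counterpart.  Per fragment feature (delimited by its own boundary
    markers):

    * all columns unaligned                        -> novel (N)
    * aligned and unaligned runs mixed             -> hybrid (H)
    * aligned, exactly one full reference feature  -> that feature's label
    * aligned, proper subset of one feature        -> segment (S)
    * aligned, spanning two or more features       -> join (J)

    Any unaligned run of at least one column inside an otherwise aligned
    feature makes it hybrid (the strictest reading; no tolerance is
    applied).  Non-standard labels are numbered by 5'->3' appearance.
    """
    if len(pairing) != fragment_gen.n_columns:
        raise AtlasError("pairing length must equal fragment column count")
    aligned_vals = [p for p in pairing if p is not None]
    if any(b <= a for a, b in zip(aligned_vals, aligned_vals[1:])):
        raise AtlasError("pairing is not monotonic")

    ref_feat_of_col: dict[int, str] = {}
    ref_cols_of_feat: dict[str, set[int]] = {}
    for label, s, e in reference_gen.feature_intervals():
        for c in range(s, e + 1):
            ref_feat_of_col[c] = label
        ref_cols_of_feat[label] = set(range(s, e + 1))

    frag_row = fragment_gen.rows[fragment_gen.reference_allele]

    def run_nt(cols: Iterable[int]) -> int:
        return sum(1 for c in cols if frag_row[c] not in ".*")

    features: list[str] = []
    annotation: dict[str, str] = {}
    counters = {cls: 0 for cls in NONSTANDARD_CLASSES}

    for _, s, e in fragment_gen.feature_intervals():
        cols = list(range(s, e + 1))
        # contiguous aligned/unaligned runs, ignoring pure-indel columns
        runs: list[tuple[bool, list[int]]] = []
        for c in cols:
            if frag_row[c] == ".":
                continue
            aligned = pairing[c] is not None
            if runs and runs[-1][0] == aligned:
                runs[-1][1].append(c)
            else:
                runs.append((aligned, [c]))
        aligned_ref = [pairing[c] for c in cols if pairing[c] is not None and frag_row[c] != "."]
        has_unaligned = any(not a for a, _ in runs)

        if not aligned_ref:
            cls_label = _next(counters, "N")
            annotation[cls_label] = (
                f"{cls_label} is {run_nt(cols)} nucleotides of novel sequence."
            )
            features.append(cls_label)
            continue
        touched = []
        for rc in aligned_ref:
            f = ref_feat_of_col[rc]
            if not touched or touched[-1] != f:
                touched.append(f)
        if has_unaligned:
            cls_label = _next(counters, "H")
            parts = []
            for aligned, rcols in runs:
                if aligned:
                    feats = sorted({ref_feat_of_col[pairing[c]] for c in rcols})
                    parts.append(
                        f"{run_nt(rcols)} nucleotides aligning within {'/'.join(feats)}"
                    )
                else:
                    parts.append(f"{run_nt(rcols)} nucleotides of novel sequence")
            annotation[cls_label] = f"{cls_label} is " + " followed by ".join(parts) + "."
            features.append(cls_label)
        elif len(touched) == 1:
            feat = touched[0]
            covered = {pairing[c] for c in cols if pairing[c] is not None and frag_row[c] != "."}
            ref_cols = {
                c
                for c in ref_cols_of_feat[feat]
                if reference_gen.rows[reference_gen.reference_allele][c] != "."
            }
            if covered >= ref_cols:
                features.append(feat)
            else:
                cls_label = _next(counters, "S")
                annotation[cls_label] = (
                    f"{cls_label} is {len(covered)} of {len(ref_cols)} "
                    f"nucleotides of {feat}."
                )
                features.append(cls_label)
        else:
            cls_label = _next(counters, "J")
            spans = []
            for f in touched:
                n = sum(
                    1
                    for c in cols
                    if pairing[c] is not None
                    and frag_row[c] != "."
                    and ref_feat_of_col[pairing[c]] == f
                )
                spans.append(f"{n} nucleotides of {f}")
            annotation[cls_label] = (
                f"{cls_label} joins " + " and ".join(spans) + "."
            )
            features.append(cls_label)

    return FeatureSet(
        gene=fragment_gen.locus,
        reference_gene=reference_gen.locus,
        features=features,
        annotation=annotation,
        version=fragment_gen.version,
    )


def _next(counters: dict[str, int], cls: str) -> str:
    counters[cls] += 1
    return f"{cls}.{counters[cls]}"


# ---------------------------------------------------------------------------
# gazetteer


@dataclass
class Gazetteer:
    categories: dict[str, list[str]]
    version: str = ""

    def __getitem__(self, key: str) -> list[str]:
        return self.categories[key]

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "categories": self.categories}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Gazetteer":
        payload = json.loads(text)
        return cls(categories=payload["categories"], version=payload["version"])


def build_gazetteer(
    inventory: Mapping[str, set[str]],
    metadata: Mapping[str, GeneMetadata],
    version: str = "",
) -> Gazetteer:
    """Organise curated genes into the package's named categories.

    Alignment-availability categories come from ``inventory``; status,
    class and map order from the packaged gene metadata.  The chromosomal
    ``map`` covers every curated gene centromeric to telomeric, rendering
    the order-ambiguous DRB clusters as single merged entries
    (``DRB3/4/5``, ``DRB6/7``).
    """
    missing = sorted(set(inventory) - set(metadata))
    if missing:
        raise AtlasError(f"genes missing from gene metadata: {', '.join(missing)}")
    genes = sorted(inventory)

    def having(at: str) -> list[str]:
        return [g for g in genes if at in inventory[g]]

    def status(s: str) -> list[str]:
        return [g for g in genes if metadata[g].status == s]

    cats: dict[str, list[str]] = {
        "all": genes,
        "align": genes,
        "gen": having("gen"),
        "nuc": having("nuc"),
        "prot": having("prot"),
        "codon": having("codon"),
        "nogen": [g for g in genes if "gen" not in inventory[g]],
        "nonuc": [g for g in genes if "nuc" not in inventory[g]],
        "noprot": [g for g in genes if "prot" not in inventory[g]],
        "expressed": status("expressed"),
        "pseudogene": status("pseudogene"),
        "gene_fragment": status("gene_fragment"),
        "classI": [g for g in genes if metadata[g].hla_class == "I"],
        "classII": [g for g in genes if metadata[g].hla_class == "II"],
        "classical": [g for g in genes if metadata[g].classical],
        "nonclassical": [
            g for g in genes if metadata[g].status == "expressed" and not metadata[g].classical
        ],
        "hla_loci": [g for g in genes if g not in NON_HLA_GENES],
        "nonhla_loci": [g for g in genes if g in NON_HLA_GENES],
    }

    ordered = sorted(metadata.values(), key=lambda m: (m.map_index, m.gene))
    chromosomal: list[str] = []
    seen_groups: set[str] = set()
    for m in ordered:
        if m.merged_map_group:
            if m.merged_map_group not in seen_groups:
                chromosomal.append(m.merged_map_group)
                seen_groups.add(m.merged_map_group)
        else:
            chromosomal.append(m.gene)
    cats["map"] = chromosomal

    assert set(cats) == set(GAZETTEER_CATEGORIES)
    return Gazetteer(categories=cats, version=version)
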