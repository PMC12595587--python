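"""Seeded synthetic corpora emulating the upstream data formats.

Every generator returns both the emitted text (in the exact dialect the
package's readers consume) and an independently-constructed ground truth,
so parsers can be checked against known answers entirely offline.  The
alignment emitter here deliberately does *not* call
:func:`hlakit.imgt_io.write_alignment`; it formats blocks from the ground
truth by its own code so that round-trip tests compare two independent
paths through the dialect.

Same seed, same output, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imgt_io import (
    AlignmentTable,
    AlleleHistory,
    Boundary,
    release_to_branch,
    _boundary_feature_labels,
)
from .names import AlleleName, format_label, next_position

_AA = "ARNDCQEGHILKMFPSTWYV"
_NT = "ACGT"

#: (latitude, longitude) of populated land locations the frequency fixtures
#: sample population coordinates from (keeps fixture maps on the land mask)
LAND_SITES = [
    (52.5, 13.4), (48.9, 2.3), (40.4, -3.7), (55.8, 37.6), (41.0, 29.0),
    (30.0, 31.2), (9.0, 38.7), (-1.3, 36.8), (-26.2, 28.0), (6.5, 3.4),
    (28.6, 77.2), (39.9, 116.4), (35.7, 139.7), (13.8, 100.5), (-6.2, 106.8),
    (37.6, 127.0), (55.7, 12.6), (19.4, -99.1), (4.7, -74.1), (-12.0, -77.0),
    (-34.6, -58.4), (-23.6, -46.6), (45.5, -73.6), (40.7, -74.0), (34.1, -118.2),
    (61.2, -149.9), (64.1, -21.9), (-33.9, 151.2), (-37.8, 145.0), (51.5, -0.1),
    (59.3, 18.1), (47.5, 19.0), (44.4, 26.1), (31.2, 121.5), (23.1, 113.3),
    (10.8, 106.7), (33.7, 73.1), (35.7, 51.4), (15.6, 32.5), (-4.3, 15.3),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic corpus; defaults give a small mixed corpus."""

    seed: int = 0
    loci: tuple[str, ...] = ("A", "C")
    alleles_per_locus: int = 8
    feature_lengths: tuple[int, ...] = (30, 24, 18, 36, 21)  # U.5 E.1 I.1 E.2 U.3
    variant_density: float = 0.08
    n_insertions: int = 1
    n_late: int = 1
    n_early: int = 1
    block_width: int = 60
    n_populations: int = 12
    concentration: float = 1.0
    migrant_fraction: float = 0.25
    version: str = "3.99.0"


# ---------------------------------------------------------------------------
# allele names


def _allele_names(rng: np.random.Generator, locus: str, n: int) -> list[str]:
    """Reference first (always 4-field), then unique names of varied depth."""
    if n < 1:
        raise ValueError("need at least one allele (the reference)")
    names = [f"{locus}*01:01:01:01"]
    seen = {(1, 1)}
    while len(names) < n:
        fam, prot = int(rng.integers(1, 30)), int(rng.integers(1, 99))
        if (fam, prot) in seen:
            continue
        seen.add((fam, prot))
        depth = int(rng.choice([2, 3, 4]))
        fields = [f"{fam:02d}", f"{prot:02d}", "01", "01"][:depth]
        suffix = "N" if rng.random() < 0.1 else ""
        names.append(f"{locus}*{':'.join(fields)}{suffix}")
    return names


# ---------------------------------------------------------------------------
# alignment fixture


def make_alignment_fixture(
    spec: FixtureSpec = FixtureSpec(),
    locus: str | None = None,
    align_type: str = "gen",
    start_label: int | None = None,
) -> tuple[str, AlignmentTable]:
    """Emit IMGT-dialect alignment text plus its ground-truth table.

    The alignment has the boundary structure given by
    ``spec.feature_lengths`` (alternating feature lengths; for genomic
    alignments 5'UTR, exons/introns, 3'UTR), insertion columns with
    fractional position labels, late-entering and early-terminating
    alleles, and random substitutions at ``spec.variant_density``.
    """
    rng = np.random.default_rng(spec.seed)
    locus = locus or spec.loci[0]
    n = spec.alleles_per_locus
    names = _allele_names(rng, locus, n)
    alphabet = _AA if align_type == "prot" else _NT

    n_base = sum(spec.feature_lengths)
    ref_base = [alphabet[int(k)] for k in rng.integers(0, len(alphabet), n_base)]
    rows_base = [list(ref_base) for _ in range(n)]
    for i in range(1, n):
        for j in range(n_base):
            if rng.random() < spec.variant_density:
                choices = [s for s in alphabet if s != ref_base[j]]
                rows_base[i][j] = choices[int(rng.integers(0, len(choices)))]

    # insertion columns: reference holds ".", one random later allele a symbol
    base_boundaries = np.cumsum(spec.feature_lengths)[:-1].tolist()
    insert_after = sorted(
        int(k) for k in rng.choice(np.arange(2, n_base - 2), spec.n_insertions, replace=False)
    ) if spec.n_insertions else []
    cols: list[list[str]] = []
    boundary_cols: list[int] = []
    for j in range(n_base):
        if j in base_boundaries:
            boundary_cols.append(len(cols))
        cols.append([rows_base[i][j] for i in range(n)])
        if j in insert_after:
            carrier = int(rng.integers(1, n)) if n > 1 else 0
            ins = ["."] * n
            ins[carrier] = alphabet[int(rng.integers(0, len(alphabet)))]
            cols.append(ins)
    matrix = [list(col_vals) for col_vals in zip(*cols)]
    n_cols = len(cols)

    # late entries / early terminations (never the reference)
    candidates = list(range(1, n))
    rng.shuffle(candidates)
    for i in candidates[: spec.n_late]:
        cut = int(rng.integers(1, max(2, n_cols // 2)))
        matrix[i][:cut] = ["*"] * cut
    for i in candidates[spec.n_late : spec.n_late + spec.n_early]:
        cut = int(rng.integers(1, max(2, n_cols // 2)))
        matrix[i][n_cols - cut :] = ["*"] * cut

    ref_row = matrix[0]
    if start_label is None:
        start_label = 1 if align_type in ("nuc", "codon") else -spec.feature_lengths[0]
    labels: list[str] = []
    pos = None
    sub = 0
    for sym in ref_row:
        if sym == ".":
            sub += 1
            labels.append(format_label(pos if pos is not None else 0, sub))
        else:
            pos = start_label if pos is None else next_position(pos)
            sub = 0
            labels.append(format_label(pos))

    pairs = _boundary_feature_labels(len(boundary_cols), align_type)
    truth = AlignmentTable(
        locus=locus,
        align_type=align_type,
        version=spec.version,
        reference_allele=names[0],
        column_labels=labels,
        rows={names[i]: matrix[i] for i in range(n)},
        boundary_columns=[
            Boundary(b, a, c) for (b, a), c in zip(pairs, boundary_cols)
        ],
    )
    truth.validate()
    text = _emit_blocks(truth, spec.block_width)
    return text, truth


def _emit_blocks(table: AlignmentTable, block_width: int) -> str:
    """Independent block formatter (kept separate from imgt_io's writer)."""
    word = {"prot": "Prot", "nuc": "cDNA", "codon": "cDNA", "gen": "gDNA"}[
        table.align_type
    ]
    names = table.allele_names
    ref = table.rows[table.reference_allele]
    width = max(len(x) for x in names) + 4
    bset = {b.col_index for b in table.boundary_columns}
    first = {n: min(i for i, s in enumerate(table.rows[n]) if s != "*") for n in names}
    last = {n: max(i for i, s in enumerate(table.rows[n]) if s != "*") for n in names}
    out = [f"# file: {table.locus}_{table.align_type}.txt",
           f"# version: IPD-IMGT/HLA {table.version}", ""]
    for s in range(0, table.n_columns, block_width):
        e = min(s + block_width, table.n_columns)
        anchor = next(
            (lab for lab in table.column_labels[s:e] if "." not in lab),
            table.column_labels[s],
        )
        out.append(f" {word}" + " " * (width - len(word) - 1) + str(anchor))
        for name in names:
            if first[name] >= e or last[name] < s:
                continue
            chunk = []
            for j in range(s, e):
                if j in bset:
                    chunk.append("|")
                if j > s and (j - s) % 10 == 0:
                    chunk.append(" ")
                sym = table.rows[name][j]
                if name != table.reference_allele and sym == ref[j] and sym != "*":
                    sym = "-"
                chunk.append(sym)
            out.append(f" {name}" + " " * (width - len(name) - 1) + "".join(chunk))
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# allele-list history fixture


def make_history_fixture(
    spec: FixtureSpec = FixtureSpec(),
    releases: tuple[str, ...] = ("3.61.0", "3.60.0", "3.59.0"),
    n_accessions: int = 20,
    rename_prob: float = 0.2,
    delete_prob: float = 0.15,
) -> tuple[str, AlleleHistory]:
    """Emit an allele-list history CSV plus ground truth.

    Releases are listed newest first, as upstream.  Some accessions are
    renamed at a scripted release and some stop appearing (deleted); the
    truth records exactly which name each accession bears in each release.
    """
    rng = np.random.default_rng(spec.seed + 1)
    chrono = list(releases)[::-1]  # oldest -> newest
    locus = spec.loci[0]
    table: dict[str, dict[str, str]] = {}
    used: set[str] = set()

    for k in range(n_accessions):
        acc = f"HLA{k + 1:05d}"
        name = _fresh(rng, locus, used)
        entry: dict[str, str] = {}
        alive_until = len(chrono)
        if rng.random() < delete_prob:
            alive_until = int(rng.integers(1, len(chrono)))
        rename_at = None
        if rng.random() < rename_prob and alive_until > 1:
            rename_at = int(rng.integers(1, alive_until))
        for idx, rel in enumerate(chrono[:alive_until]):
            if rename_at is not None and idx == rename_at:
                name = _fresh(rng, locus, used)
            entry[rel] = name
        table[acc] = entry

    truth = AlleleHistory(
        version_list=list(releases), table=table, source_version=releases[0]
    )
    lines = ["HLA_ID," + ",".join(release_to_branch(r) for r in releases)]
    for acc, entry in table.items():
        lines.append(acc + "," + ",".join(entry.get(r, "") for r in releases))
    return "\n".join(lines) + "\n", truth


def _fresh(rng: np.random.Generator, locus: str, used: set[str]) -> str:
    while True:
        nm = f"{locus}*{int(rng.integers(1, 80)):02d}:{int(rng.integers(1, 300)):02d}"
        if nm not in used:
            used.add(nm)
            return nm


# ---------------------------------------------------------------------------
# frequency fixtures


def make_frequency_fixture(
    spec: FixtureSpec = FixtureSpec(),
    alleles_by_locus: dict[str, list[str]] | None = None,
    planted: tuple[str, str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Dirichlet-distributed population frequency tables with a known truth.

    Returns ``(frequency_table, haplotype_table, truth)``.  Per population
    and locus, two-field allele frequencies are drawn from a symmetric
    Dirichlet (concentration from the spec); ``planted = (locus, allele,
    freq)`` boosts one allele to a known frequency in one non-migrant
    population, giving map tests an analytic argmax.  A ``migrant_fraction``
    of populations is flagged admixed.  Haplotype records mix two- and
    three-field names across populations, as real multi-source haplotype
    compilations do.
    """
    rng = np.random.default_rng(spec.seed + 2)
    if alleles_by_locus is None:
        alleles_by_locus = {
            locus: sorted(
                {
                    AlleleName.parse(nm).truncate(2).raw
                    for nm in _allele_names(rng, locus, spec.alleles_per_locus)
                }
            )
            for locus in spec.loci
        }
    n_pop = spec.n_populations
    site_idx = rng.choice(len(LAND_SITES), size=n_pop, replace=n_pop > len(LAND_SITES))
    pops = []
    for i in range(n_pop):
        lat, lon = LAND_SITES[int(site_idx[i])]
        migrant = i >= n_pop - round(spec.migrant_fraction * n_pop)
        pops.append((f"Pop{i + 1:02d}", lat, lon, migrant))

    records = []
    truth: dict = {"frequencies": {}, "planted": None}
    for pop, lat, lon, migrant in pops:
        for locus, alleles in alleles_by_locus.items():
            freqs = rng.dirichlet([spec.concentration] * len(alleles))
            for allele, f in zip(alleles, freqs):
                truth["frequencies"][(pop, locus, allele)] = float(f)
                records.append(
                    {
                        "popname": pop,
                        "latit": lat,
                        "longit": lon,
                        "locus": locus,
                        "allele": allele,
                        "frequency": float(f),
                        "sample_size": int(rng.integers(50, 2000)),
                        "complex": "mig" if migrant else "",
                    }
                )
    freq = pd.DataFrame.from_records(records)

    if planted is not None:
        locus, allele, boost = planted
        host = next(p for p, *_rest, m in pops if not m)
        sel = (freq["popname"] == host) & (freq["locus"] == locus)
        block = freq.loc[sel].copy()
        if allele not in set(block["allele"]):
            raise ValueError(f"planted allele {allele} not in fixture locus {locus}")
        rest = block["allele"] != allele
        others = block.loc[rest, "frequency"]
        block.loc[rest, "frequency"] = others / others.sum() * (1 - boost)
        block.loc[~rest, "frequency"] = boost
        freq.loc[sel, "frequency"] = block["frequency"]
        for _, r in block.iterrows():
            truth["frequencies"][(host, locus, r["allele"])] = float(r["frequency"])
        truth["planted"] = {"population": host, "locus": locus,
                            "allele": allele, "frequency": boost}

    freq["migrant"] = freq["complex"].str.strip().str.lower().isin({"mig"})

    # haplotype table over the first two fixture loci, mixed name depth
    loci = list(alleles_by_locus)[:2] if len(alleles_by_locus) >= 2 else list(alleles_by_locus)
    hap_records = []
    for k, (pop, lat, lon, _m) in enumerate(pops):
        depth = 3 if k % 4 == 0 else 2
        combos = []
        for _ in range(4):
            combo = []
            for locus in loci:
                a = AlleleName.parse(
                    alleles_by_locus[locus][int(rng.integers(0, len(alleles_by_locus[locus])))]
                )
                if depth == 3 and a.n_fields == 2:
                    a = AlleleName(a.locus, a.fields + ("01",), a.suffix, a.prefix)
                combo.append(a.raw)
            combos.append("~".join(combo))
        combos = sorted(set(combos))
        hfreqs = rng.dirichlet([1.0] * len(combos)) * rng.uniform(0.5, 0.95)
        for hap, f in zip(combos, hfreqs):
            hap_records.append(
                {
                    "population": pop,
                    "haplotype": hap,
                    "frequency": float(f),
                    "sample_size": int(rng.integers(100, 3000)),
                    "latit": lat,
                    "longit": lon,
                }
            )
    haplo = pd.DataFrame.from_records(hap_records)
    truth["populations"] = [
        {"population": p, "latitude": la, "longitude": lo, "migrant": m}
        for p, la, lo, m in pops
    ]
    return freq, haplo, truth


# ---------------------------------------------------------------------------
# corpus on disk


def write_fixture_corpus(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete offline test corpus (alignments, history, tables)."""
    spec = FixtureSpec(seed=seed)
    out_dir = Path(out_dir)
    (out_dir / "alignments").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    align_truth: dict[str, list[str]] = {}
    for li, locus in enumerate(spec.loci):
        for ti, align_type in enumerate(("gen", "nuc", "prot")):
            text, truth = make_alignment_fixture(
                FixtureSpec(seed=seed + 10 * li + ti + 1, loci=(locus,)),
                locus=locus,
                align_type=align_type,
            )
            p = out_dir / "alignments" / f"{locus}_{align_type}.txt"
            p.write_text(text)
            paths[f"{locus}_{align_type}"] = p
            if align_type == "prot":
                align_truth[locus] = sorted(
                    {AlleleName.parse(n).truncate(2).raw for n in truth.allele_names}
                )
    text, _ = make_history_fixture(spec)
    paths["history"] = out_dir / "Allelelist_history.txt"
    paths["history"].write_text(text)
    freq, haplo, _ = make_frequency_fixture(spec, alleles_by_locus=align_truth)
    paths["frequencies"] = out_dir / "frequencies.tsv"
    freq.drop(columns=["migrant"]).to_csv(paths["frequencies"], sep="\t", index=False)
    paths["haplotypes"] = out_dir / "haplotypes.tsv"
    haplo.to_csv(paths["haplotypes"], sep="\t", index=False)
    return paths
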