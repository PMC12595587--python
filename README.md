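# hlakit

Computable IPD-IMGT/HLA resources and global HLA frequency heatmaps, in
Python.

The HLA genes (chromosome 6p21.3) are the most polymorphic loci in the human
genome: tens of thousands of named alleles, curated quarterly by the
IPD-IMGT/HLA Database and distributed as static text files - block-formatted
multiple sequence alignments, an allele-name history, and per-release allele
lists.  Those files are written for human eyes.  `hlakit` turns them into
data structures you can compute on, and turns population allele-frequency
tables into global heatmaps:

- **`hlakit.imgt_io`** parses the IMGT alignment dialect (blocks of 50-100
  positions; `-` = identity to the reference, `.` = indel, `*` = unknown,
  `|` = gene-feature boundary) into *alignment tables*: one allele per row,
  one aligned position per column, fully expanded, with fractional labels
  (`25.1`) for insertion columns and no position 0.  It also reads
  `Allelelist_history.txt` (accession x release -> allele name) and fetches
  per-release files from the ANHIG/IMGTHLA repository (one git branch per
  release), with a mandatory on-disk cache.
- **`hlakit.nomenclature`** validates allele names against a release and
  translates alleles, GL Strings, GL String Codes and whole genotype tables
  between releases via their stable accessions (e.g. `C*03:12` before 2015
  ↔ `C*03:307` after).
- **`hlakit.atlas`** charts gene-feature boundaries per alignment (the
  boundary's flanking positions and, for coding alignments, its codon on
  the mature protein), measures gene bodies, classifies the features of
  pseudogenes and gene fragments against a genomic reference - *hybrid*
  (H), *join* (J), *novel* (N) and *segment* (S) features, numbered 5'→3' -
  and organises curated genes into a 19-category gazetteer.
- **`hlakit.seqquery`** answers positional questions: which residues does
  an allele carry at chosen positions (`alignment_search`), which alleles
  carry a motif (`motif_match`), what is the residue distribution at a
  position (`query_positions`), plus custom multi-locus mini-alignments.
- **`hlakit.freqmap`** implements PALM (Population Allele Locating
  Mapmaker): variant specifier + population frequency table → per-population
  point values → inverse-distance-weighted global grid (haversine distance,
  power 2, 1° cells, 2000 km cutoff, coastline mask) → colour or greyscale
  map with a white dot per population.  Motif maps sum the frequencies of
  every allele carrying the motif; haplotype maps extract and truncate
  alleles from longer multi-gene haplotype records.
- **`hlakit.fixtures`** generates seeded synthetic corpora in all four
  input dialects with known ground truth, so the whole pipeline is testable
  offline.
- **`hlakit.cli`** exposes it all as `hlakit update|query|translate|atlas|map|fixtures`.

## Worked example

```python
from hlakit.fixtures import FixtureSpec, make_alignment_fixture, make_frequency_fixture
from hlakit import seqquery, freqmap

# a seeded synthetic DRB1 protein alignment with known ground truth
text, prot = make_alignment_fixture(FixtureSpec(seed=42, loci=("DRB1",)),
                                    align_type="prot")

# read the reference allele's residues at three positions, then find every
# allele sharing that motif (reported as deduplicated two-field names)
motif = "DRB1*" + seqquery.alignment_search(prot, prot.reference_allele, [1, 5, 9])
print(motif)                                  # DRB1*1E~5I~9N
print(seqquery.motif_match(motif, prot, truncate_to=2))
# ['DRB1*01:01', 'DRB1*03:76', 'DRB1*13:09N', 'DRB1*16:96', 'DRB1*27:40']

# a frequency table with a signal planted at 0.5 in one population,
# mapped with migrant populations filtered out
freq, haplo, truth = make_frequency_fixture(FixtureSpec(seed=42, loci=("A", "C")),
                                            planted=("A", "A*01:01", 0.5))
res = freqmap.palm("A*01:01", freq, kind="allele", resolution=2.0,
                   out_path="example_map.png")
print(res.audit["n_populations"], res.audit["max_point_value"], res.audit["vmax"])
# 9 0.5 0.5
print(res.audit["populations_dropped_migrant"])
# ['Pop10', 'Pop11', 'Pop12']
```

The printed motif is the reference allele's residues at positions 1, 5
and 9; the match list is every allele in the alignment carrying all three
residues, truncated to two name fields (expression suffixes such as `N`
survive truncation).  The map audit shows nine populations used, three
admixed populations dropped, and a colour scale running 0 → 0.5 (the
planted maximum); `example_map.png` holds the rendered heatmap.

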