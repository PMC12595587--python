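# Methods

## The IMGT alignment dialect and its table form

IPD-IMGT/HLA alignments arrive as text blocks of 50-100 positions: a
position-label line, then one line per allele, the first sequence of the
first block being the reference.  Within sequence lines `-` means identity
to the reference, `.` an indel, `*` unknown/unsequenced sequence, `X` a
stop codon (protein alignments), and `|` marks a gene-feature boundary.
`hlakit` flattens these into an alleles x positions matrix with every
identity dash expanded.  Conventions the source files leave implicit, fixed
here:

- **Position labels** are synthesised by walking reference columns from the
  first anchor number on the first block's label line.  There is no
  position 0 (numbering runs ..., -2, -1, 1, 2, ...); columns where the
  reference carries `.` are insertion columns labelled `n.1, n.2, ...`
  after position `n`.
- **Padding**: alleles first appearing in a later block are left-padded
  with `*` (unknown), never `-`; rows that end early are right-padded with
  `*`.  A row longer than its block is an error naming the allele and
  block.
- **Codon tables** are derived from coding-nucleotide tables (three
  nucleotide columns per codon from cDNA position 1, insertion columns
  attached to the codon of their anchor), not parsed separately: the source
  encodes both in one file.
- **Writer**: tables serialise back to the block dialect; writing and
  re-parsing reproduces the table exactly.  The synthetic-corpus emitter in
  `hlakit.fixtures` formats blocks by independent code so round-trip tests
  compare two implementations of the dialect, not one with itself.

## Release translation

Allele names change between quarterly releases; accessions do not.  The
allele-list history maps accession x release -> name, so translation is:
look the name up in the source release, take its accession, read off the
target release's name.  An accession with no entry in the target release is
*absent* (deleted/renamed away) - distinct from a name that was never valid
in the source release, which is an error.  Truncated (1-2 field) names are
expanded to every matching full name, each is translated and re-truncated,
and the unique survivor is returned; disagreement is an explicit ambiguity
error.  Expression suffixes survive truncation (`B*13:07:01N` -> `B*13:07N`).

GL Strings are translated leaf by leaf with structure preserved
(delimiters `^ | + ~ /` in precedence order).  The behaviour for leaves
absent from the target release is an explicit parameter - `drop` (prune the
leaf and any emptied branch), `keep`, or `fail` (default; the upstream
tooling's behaviour for deleted alleles is unspecified, so the safe default
is loud).  GL String Code namespaces are opaque text; only the version
field and allele leaves are rewritten.  `HLA-` prefixes are preserved as
read.

## Feature atlas and fragment classification

Boundary records store the feature labels on both sides, the flanking
column labels, and - for coding-nucleotide alignments - the boundary's
codon.  Codon convention: a boundary on a codon multiple belongs to the
completed codon before it (a 6-nt exon ends in codon 2); a mid-codon
boundary belongs to the codon containing the first nucleotide after it.
Codons are numbered on the mature protein, so the signal-peptide length
(count of negative protein positions, or an explicit `leader_codons`) is
subtracted; e.g. a class I boundary between cDNA 619 and 620 with a
24-codon leader lies in mature codon ceil(620/3) - 24 = 183.

The gene body is the contiguous exon+intron span: non-indel symbols between
the 5'UTR/Exon-1 and last-exon/3'UTR boundaries of a genomic row.

Pseudogene/gene-fragment features are classified against a genomic
reference (HLA-C for class I fragments - the longest class I gene body -
and DPA1/DPB1 for the DP pseudogenes) through an explicit column pairing.
Per fragment feature: fully unaligned -> novel (N); mixed aligned/unaligned
runs -> hybrid (H); exactly one full reference feature -> that feature's
standard label; a proper subset of one feature -> segment (S); spanning two
or more features through their boundary -> join (J).  Any unaligned run of
one or more columns makes a feature hybrid - the strictest reading, since
no tolerance is documented upstream.  H/J/N/S labels are numbered by 5'→3'
appearance; a fragment identical to its reference recovers exactly the
standard labels (identity limit, tested).  Pairings come from shared
multiple-alignment coordinates when available; otherwise
`pairing_from_sequences` estimates one by semi-global edit-distance
alignment, accepting only runs of ≥30 columns at ≥70% identity as aligned -
a heuristic stand-in for curated pairings, and deliberately pluggable.
Annotations report measured run structure (lengths and reference features);
they are not guaranteed to match curated free-text descriptions verbatim.

## Gazetteer

Genes are organised into a frozen 19-category roster: `all, align, gen,
nuc, prot, codon, nogen, nonuc, noprot, expressed, pseudogene,
gene_fragment, classI, classII, classical, nonclassical, hla_loci,
nonhla_loci, map`.  Alignment-availability categories derive from the file
inventory (codon availability implied by nuc for expressed genes); status,
class and chromosomal order come from a packaged gene-metadata table
(`data/gene_metadata.tsv`) that replaces scraping the curators' website.
The `map` category lists genes centromeric to telomeric; the DRB clusters
whose order is ambiguous under structural variation are rendered as single
merged entries `DRB3/4/5` and `DRB6/7`.  Only structural properties of the
order (merging, the HLA-R/HLA-Y adjacency on their shared insertion
variant) are load-bearing; the exact rank of every gene is reference data,
not an algorithmic claim.

## Frequency maps

`select_variant` turns a specifier into one value per population:

- **allele**: the allele's recorded frequency; 0 where the population is
  typed at the locus but lacks the allele.  Specifier names are truncated
  to each record's field depth before comparison.
- **motif**: the sum of frequencies of every allele in the table found by
  `motif_match` over the locus protein alignment, with matches truncated to
  the table's recorded depth before joining (additivity is exact and
  tested).
- **haplotype**: the sum of haplotype-record frequencies whose alleles -
  extracted from possibly longer multi-gene haplotypes and truncated to the
  requested field depth - equal the spec.  Coarser specs are pointwise ≥
  any finer spec they contain (monotonicity, tested).  Populations whose
  records lack a requested locus or depth are excluded rather than zeroed.

Populations flagged migrant/admixed (Solberg `complex` codes `mig/adm/...`,
mapped in `freqmap.MIGRANT_CODES`) are dropped when `filter_migrant` is
set; a variant below 1e-4 everywhere is refused unless low-frequency maps
are explicitly enabled; a variant observed nowhere is a distinct
"not observed" outcome.

**Gridding** is inverse-distance weighting on great-circle (haversine)
distance: power 2, 1° cells, with cells farther than 2000 km from every
population masked, plus a sea mask from packaged coarse land polygons
(synthetic, hand-digitised outlines; small islands and fine coastline are
absent).  All four parameters are exposed.  IDW is a convex combination, so
the surface never overshoots the point-value range - a documented
divergence from spline-based gridding toolchains, whose tension and
smoothing parameters are not published; consequently rendered surfaces
resemble but do not pixel-match maps produced with those toolchains, and
map correctness is defined on point values and mask topology instead.  The
cell nearest each population is set to that population's exact value (mean
if several share a cell) and is never masked.

**Rendering**: colour maps run blue (low) to red (high), greyscale white to
black; populations are white dots; the colour bar runs 0 to the grid
maximum - the data maximum by default, or fixed at 1.0 (`map_scale=False` /
unit scale) so complementary variants share one scale.  Hardy-Weinberg
helpers (`hom = f²`, `het = 2fg`) are estimates under random mating, not
observed genotype counts.

`palm` composes the three stages and audits matched alleles, populations
used and dropped, and the scale maximum.  Protein alignments are cached per
locus, so the first motif map for a locus costs an alignment build and
subsequent maps do not.

## Synthetic corpus

The fixture generators define the test conditions: alignments of 8 alleles
over a 5-feature gene (UTR/exon/intron lengths 30/24/18/36/21 nt),
substitution density 0.08, one insertion column, one late-entering and one
early-terminating allele, block width 50-100; histories of 3 releases with
rename probability 0.2 and deletion probability 0.15; frequency tables of
12 populations at real land coordinates with symmetric Dirichlet(1)
frequencies per locus, a 25% admixed fraction, and an optionally planted
high-frequency allele giving map tests an analytic argmax; haplotype tables
mixing two- and three-field names across populations, as multi-source
haplotype compilations do.  These sizes keep the full offline suite to a
few seconds while exercising every dialect feature; they do not emulate
linkage disequilibrium, typing error or ascertainment, so passing tests
demonstrate correctness of the machinery, not realism of the genetics.
Everything is seeded: same seed, same bytes.

## Known limitations

- The sea mask is deliberately coarse; islands smaller than the polygon set
  render as sea.
- Codon numbering for loci without a protein alignment defaults to no
  leader correction unless `leader_codons` is given.
- `pairing_from_sequences` is a heuristic; curated fragment pairings are
  preferred where they exist.
- Only the IMGT text dialect is read - MSF/FASTA/PIR/XML/EMBL forms carry
  less positional information and are out of scope, as are UNIFORMAT and
  analysis-format interconversions beyond the simple tabular genotype
  dialect.
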