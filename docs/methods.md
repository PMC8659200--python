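# Methods

`cyclomine` reimplements, as one offline and fully deterministic
pipeline, the transporter-guided strategy for mining bacterial genomes
for head-to-tail cyclized (circular) bacteriocins: transporter proteins
of characterized circular bacteriocins are used as search drivers, the
genomic neighborhood of every hit is examined for the minimal
biosynthetic gene content, and the surviving precursor peptides are
classified, networked, and placed on a tree. This note records the
models, the defaults, and the choices made where the design was open.

## Homology search

The driver-sequence search is Smith–Waterman local alignment with
affine gaps over BLOSUM62 (gap open 11, extend 1; a gap of length L
costs `open + (L-1)·extend`), computed by Biopython's `PairwiseAligner`
C kernel behind the package's own result type. `X` (ambiguous
translation) scores 0 against everything. Percent identity is
`100 · n_identical / n_aligned_columns` where columns pairing a residue
with an internal gap count in the denominator — the convention matters
near the 50% network threshold, so it is fixed once, here.

A web BLAST search ranks hits by E-value; a local all-by-all search has
no database context, so hits are filtered instead by explicit,
deterministic thresholds: minimum identity 30%, minimum query coverage
0.5, minimum raw score 50 (all configurable). Tie-breaking among
equal-scoring alignments is the aligner's deterministic traceback
order; results never depend on input ordering.

## Cluster mining

Each transporter hit anchors a neighborhood window of up to k = 10
annotated genes per side (a common choice for RiPP neighborhoods),
padded 1 kb into the flanking intergenic space so that an unannotated
precursor adjacent to the outermost gene — up to a 150-aa CDS plus its
spacer — is still visible. Overlapping windows collapse onto the
best-scoring anchor, so a cluster with several transporter genes is
reported once.

Precursors are frequently unannotated, so the window DNA is scanned in
all six frames for ORFs starting at ATG/GTG/TTG and ending at the first
in-frame stop, keeping the longest ORF per stop and suppressing ORFs
wholly contained in a same-strand annotated CDS. Precursor length
bounds default to 25–150 aa (characterized leaders span 2–48 residues;
cores roughly 33–70).

Every window protein is aligned against the seed entries of each role
(precursor, transporter, SpoIIM, Yip1, peptidase); a gene carries at
most one role, resolved by highest raw score with ties favoring
precursor > SpoIIM > transporter (the precursor is the scarce signal).
The co-occurrence verdict is `pass` iff the window contains a
seed-supported precursor, a SpoIIM gene, and a transporter — the
minimal content shared by every characterized cluster. Accessory genes
(Yip1, peptidases by homology; transposases by annotation text, since
they have no seed role) are reported as flags and never affect the
verdict.

Small ORFs that merely *look* like precursors (length in bounds,
GRAVY ≥ −0.5) are abundant in any window — reverse-strand shadows of
real genes produce them freely — so such candidates are reported with a
`heuristic_only` flag but do not satisfy the filter by themselves.
Requiring seed homology for the precursor role is what keeps decoy
neighborhoods (specificity) out while costing nothing at the identity
levels the pipeline targets (≥ 60% recovery is exercised end-to-end).

## Physicochemistry and subgroup classification

GRAVY is mean Kyte–Doolittle hydropathy (X excluded from numerator and
length). Net charge is a Henderson–Hasselbalch summation with the
EMBOSS pKa set (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5;
termini 8.6/3.6; table swappable). Because circular peptides join their
termini in an amide bond, `cyclic` mode drops both terminal groups. The
isoelectric point is found by bisection on [0.001, 13.999] to 1e−4; a
peptide whose charge never crosses zero (e.g. a cyclic core with basic
residues only) has *no* pI, reported as undefined rather than an error.

Subgroup i circular bacteriocins are highly cationic (reported pI
typically above 10); subgroup ii are near-neutral and hydrophobic.
Classification is driven by net charge at pH 7 on the cyclic core —
not pI, which is undefined exactly for the most cationic cores — with
defaults: subgroup i at charge ≥ +2; subgroup ii within [−1, +1] and
GRAVY ≥ 0; anything else ambiguous. The thresholds reproduce all 19
bundled reference labels and are configurable.

Whether hydropathy should be computed on the precursor or the mature
core is ambiguous in practice; the default is the core (obtained by
cleavage transfer when the group has a characterized anchor, otherwise
the full precursor, flagged), switchable via `profile_on_core`.

## Sequence similarity network

Nodes are unique precursor sequences (exact-string deduplication, with
multiplicity tracking producers); edges require local-alignment
identity ≥ 50% and raw score ≥ 60. The score floor stands in for the
E ≤ 1e−5 pre-filter of a database-backed all-by-all: by the
Karlin–Altschul correspondence at peptide-database scale, scores in the
low tens are motif-level noise (and empirically admit 9–25-column
spurious edges between unrelated families), whereas genuine family
edges score in the hundreds. Connected components of size ≥ 2 become
groups numbered 1..n by descending size (ties by smallest member id);
size-1 components are singletons.

## Logos and cleavage transfer

Groups with ≥ 3 members are aligned with a native progressive MSA: a
UPGMA guide tree from pairwise global-identity distances, then
profile–profile Gotoh alignment under the same matrix and gap
parameters as the pairwise stage (for two sequences this reduces
exactly to pairwise global alignment). A dedicated MSA program would
produce marginally better alignments; the native aligner keeps the
pipeline dependency-free, deterministic, and testable, which is what
the logo and cleavage stages need.

The logo matrix holds per-column residue frequencies over the 20
canonical letters (gaps and X excluded from frequencies; X counts as
gap), gap fraction, and information content `IC = log2(20) − H` in
bits, with no small-sample correction. Rendering is left to external
tools; the matrix is the contract.

Leader cleavage sites are transferred from characterized anchors: the
anchor's last leader residue maps to its alignment column, and each
member's site is the count of its own residues in columns up to that
column (a member gapped at the boundary thus reports the nearest
preceding residue). Anchor leader lengths ship as an editable fixture
table next to the seed set; groups without a characterized anchor get
no prediction.

## Phylogeny

The tree stage is Saitou–Nei neighbor joining on distances
`d = 1 − global-identity fraction`, with deterministic tie-breaking
(smallest index pair) and negative branch estimates clamped to zero and
counted. On additive matrices NJ recovers the generating topology
exactly (property-tested on random 6-taxon trees and cross-checked
against scikit-bio's NJ). Trees are unrooted, serialized as Newick with
a basal trifurcation, plus a flat leaf-annotation table (group,
subgroup, GRAVY) for standard viewers. A maximum-likelihood tree under
a fitted substitution model would be the publication-grade choice; the
tree's role in this pipeline is visual grouping, which NJ serves at a
fraction of the cost, and the annotation table feeds any external ML
workflow.

## Synthetic data

The generator emulates the documented cluster architectures: 1–3
precursor copies (extra copies are near-identical paralogs at ~98%
identity to the first), 1–3 transporters, a SpoIIM gene, optional
Yip1/transposase/peptidase accessories, implanted on either strand into
a background of random genes (default 25 per genome, 80–350 aa) with
20–200-nt spacers, at a controlled target identity to the seed proteins
(`mutate_to_identity`: substitution positions sampled without
replacement, replacements drawn by BLOSUM exchangeability, realized
identity within ±3 points except for very short peptides, which warn).
Decoy clusters omit one required role. An in-frame stop codon is
written immediately upstream of each precursor CDS so the true ORF
boundary is exactly recoverable by scanning. Codon choice is uniform —
nothing downstream reads codon bias. Everything is deterministic under
the configured seed, and the manifest (coordinates, strands, roles,
realized identities, annotation status) is the oracle every recovery
test checks against.

The standard benchmark is 20 genomes with 6 complete clusters spanning
60–90% seed identity and varied architectures plus 4 decoys (2 missing
the precursor, 2 missing SpoIIM). What synthetic recovery does *not*
show: behavior on real annotation error modes (frameshifts, fused
genes), compositional bias of real genomes, or homologs below the
search thresholds; the generator also does not simulate reads or
realistic genome-scale gene content.

## Bundled seed set

The package ships a **synthetic stand-in** seed set
(`data/seeds_synthetic.faa` + role/cleavage tables, regenerable by
`scripts/build_seed_fixture.py`): 19 named precursors (13 subgroup i,
6 subgroup ii) with documented family structure — the six subgroup ii
peptides one mutually ≥50%-identical family with asparaginyl cleavage
sites and Ala-terminal hydrophobic cores; the amylocyclicin and
AS-48-like families cohesive; circularin A and thermocin 485 identical;
the rest singleton-like — plus per-bacteriocin transporter and SpoIIM
entries and accessory families. It is a surrogate with the documented
*properties* of the real proteins, not their sequences; replace it with
a real FASTA + role TSV via `load_seed_set(fasta, roles)` or the CLI
for production mining.

## Numerical and degenerate-input conventions

* Alignment of sequences with no positive pair score returns the empty
  local alignment (score 0) rather than an arbitrary single column.
* All tables are written fully sorted; identical inputs give
  byte-identical outputs.
* Genes translated with internal stops are kept, flagged, and excluded
  from searches (miscalled genes should not abort a run).
* Two-taxon "trees" are returned flagged rather than rejected; fewer
  than two taxa is an error.
* Problem sizes in the test suite: 1000 alignment-oracle pairs (len ≤ 6,
  with an exhaustive path-enumeration cross-check at len ≤ 4), 500
  pI-oracle peptides, 200 random component-oracle graphs, 100 random
  additive 6-taxon trees, and the 20-genome recovery benchmark.

## Known limitations

* Immunity genes are not detected (no seed family is bundled).
* The E-value-free score floor is calibrated for peptide-scale
  networks; genome-scale proteome networks would need recalibration.
* Cleavage transfer degrades with alignment quality below ~50%
  anchor identity; the confidence field reports anchor identity so
  downstream users can filter.
* The progressive MSA has no iterative refinement; deeply gapped
  families may misplace sparse columns.
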