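# Methods

This note documents the models, conventions, and design choices behind
`cngckit`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and sequence spaces

All genomic coordinates are 1-based inclusive (GFF3 native); distances such
as the 50 kb tandem rule are plain coordinate differences. Exon lists are
kept in transcription order (descending genomic order on the − strand).
RNA/DNA conversion (U↔T) is always explicit via `to_rna`/`to_dna`; the miRNA
module works in RNA space, the codon modules in DNA space. Aligned sequences
reuse the plain sequence type with `-` admitted as a gap symbol.

## Motif engine and family rule

Patterns are dash-separated PROSITE-style elements: literals, residue
classes `[ABC]`, and wildcards `X`, each optionally repeated `(n)` or
`(m,n)`. The matcher reports every start position (overlaps allowed) and,
per start, the *shortest* satisfying expansion of variable-length elements
(leftmost-shortest). This is deterministic and directly checkable against an
exhaustive enumeration oracle; alternative expansions never change
presence/absence, which is all the family rule consumes. Matching is
case-insensitive; an ambiguous `X` in the subject matches nothing.

A candidate is accepted iff its annotation row carries both the CNBD and
ion-transport domain labels, the diagnostic consensus motif matches at least
once, and the protein is ≥ 400 residues. The 400-residue floor
operationalizes "truncated": the shortest genuine member in the reference
family is 558 aa, so 400 rejects fragments without risking real members. The
calmodulin-binding-domain pattern shipped in `data/patterns.txt` is a
balanced interpretation of an ambiguously printed pattern
(`[FLY]-X(10,12)-[AFI]-R-[FY](0,1)`); it is informational only and never
used for classification, and the IQ motif likewise plays no part in the
accept/reject decision.

## Protein physicochemistry

Average (not monoisotopic) residue masses are summed plus one water; atom
counts add per-residue chain compositions plus the terminal water's three
atoms. The average residue weight is (mass − water)/length, which makes
`avg · L = 1000·MW − 18.0153` an exact identity. GRAVY is the mean
Kyte–Doolittle hydropathy; the aliphatic index follows Ikai
(X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent); the instability
index follows Guruprasad, II = (10/L)·Σ DIWV over consecutive dipeptides,
with the published DIWV table taken from Biopython's data module and the
stable/unstable call at II < 40.

Net charge uses Henderson–Hasselbalch sums over D, E, C, Y (acidic), H, K, R
(basic) and both termini. The default pKa set is Bjellqvist's (the ProtParam
convention, since that is the tool such surveys use); an EMBOSS set is
selectable, and the choice is declared in reports rather than claimed
identical to any published table. Charge is strictly decreasing in pH, so
the pI bisection root on [0, 14] (tolerance |charge| < 1e-4) is unique; the
tests verify it against a 1e-5-resolution grid scan. Net charge is reported
at pH 7.0 with one decimal.

## Ka/Ks (Nei–Gojobori 1986)

The estimator is the classic approximate method, declared rather than
inferred (the survey this reconstructs never names its estimator, and its
published values also depend on database sequences not shipped here):

- **Sites.** Per codon position, the synonymous potential is the fraction
  of the three single-nucleotide changes that preserve the amino acid;
  changes creating stop codons are excluded from the denominator. S sums
  these fractions averaged over the two sequences; N = 3·(codons) − S
  exactly.
- **Differences.** Codons differing at k positions average the synonymous/
  nonsynonymous step counts over all k! minimal mutational pathways,
  excluding pathways through stop codons (all pathways are used as a
  fallback if every one is blocked).
- **Correction.** Jukes–Cantor, d = −¾ ln(1 − 4p/3), applied to both
  proportions; p ≥ ¾ is flagged undefined instead of extrapolated.
- Gap- or stop-containing codon columns are excluded. Ka/Ks is reported
  from unrounded internals; the class is positive (>1), purifying (<1),
  neutral (=1), or undefined (Ks = 0 or saturated).

The protein aligner is Needleman–Wunsch with BLOSUM62 and a linear gap
penalty of 8, with traceback ties resolved diagonal → up → left so
alignments are reproducible; scores are verified against exhaustive
alignment enumeration at small lengths. The pipeline's all-vs-all distance
pass uses Biopython's C pairwise aligner with the same scoring for speed;
the in-package implementation remains the specified, oracle-tested
operation.

## Duplication, fractionation

Tandem duplicates: same-chromosome family pairs with an intergenic gap
(nearest feature ends, 0 when overlapping) under 50,000 bp; clusters are the
transitive closure of the pairwise relation, since published clusters of
three would otherwise fragment. Nearest-end gaps (not midpoints) read
"distance between loci" as the intergenic distance. Segmental duplicates are
taken from a syntenic-block input table — whole-genome synteny detection is
out of scope. Sub-genome fractionation counts genes per LF/MF-I/MF-II label
from an assignment table, the three-way partition left by the Brassica
whole-genome triplication.

## Phylogeny

p-distances exclude any column gapped in either sequence. Neighbor joining
is Saitou–Nei with the Studier–Keppler Q criterion; ties in Q are broken by
the smallest pair of (smallest-leaf-label) keys, and negative branch lengths
are clamped to zero with the deficit moved to the sister edge — common NJ
practice, declared because the method leaves it open. NJ on additive
matrices provably recovers the generating topology, which the test suite
exercises with random tree-generated matrices and cross-checks against
scikit-bio's implementation. Group assignment gives each query the group of
its p-distance-nearest reference anchor (ties to the lexicographically first
anchor). Bootstrap resamples alignment columns with replacement, rebuilds
NJ per replicate, and reports per-split support percentages; it is seeded
and reproducible. A maximum-likelihood tree is deliberately out of scope;
distance-based NJ is the supported builder.

## miRNA target scoring

The duplex scheme is {Watson–Crick 0, G:U wobble 0.5, mismatch 1.0},
ungapped, with the miRNA reversed to 3′→5′ against the target site 5′→3′.
This scheme was chosen because it reproduces the published duplex table
exactly: of the 11 printed rows, 9 match the printed expectation to the
digit, while seed-region-doubling variants contradict multiple rows. The two
exceptions (printed 3.0; rescored 2.5 and 3.5) have alignment strings whose
whitespace was lost in typesetting, so their column assignment is ambiguous;
they ship flagged `typeset_ambiguous` in `data/table4_duplexes.tsv` and are
excluded from exact regression. Inhibition is translational iff a mismatch
(not a wobble) falls on miRNA positions 9–11 from the 5′ end, consistent
with every printed cleavage/translation call. Expectations are therefore
always multiples of 0.5. Scanning scores every miRNA-length window and
reports those at or below the cutoff (3.0 stringent default, 5.0
permissive), sorted by (expectation, position). Target-accessibility (UPE)
energies require an RNA-folding model and are carried as annotations only.

## Gene structure

Intron phase is the cumulative upstream CDS length mod 3 at the junction,
computed on CDS segments only (the surveys draw CDS boxes; UTR handling is
out of scope). Phases are invariant under genomic translation and strand
flip because they depend only on transcription-order exon lengths.

## Expression and qPCR

Expressed calls use FPKM > threshold (default 1) in at least one tissue —
strictly greater, so a row of exact 1.0 values is not called. The log
transform is log₂(x + 1): the matrices contain zeros and the offset is
declared and configurable rather than silently assumed. Hierarchical
clustering is hand-rolled agglomerative (average = size-weighted UPGMA, or
complete linkage; euclidean or correlation distance) with ties broken by
the lowest-index pair, because library implementations do not guarantee a
documented tie order; dendrograms serialize to Newick with ultrametric
heights. The linkage/metric defaults are declared, not claimed identical to
any published heatmap.

ΔΔCt follows Livak: ΔCt = mean(Ct_target − Ct_reference) per condition,
ΔΔCt = ΔCt_treated − ΔCt_control, fold = 2^(−ΔΔCt); log₂ ratio = −ΔΔCt
exactly. A per-replicate paired mode is available by flag. Significance uses
one-way ANOVA followed by Fisher's protected LSD,
LSD = t(1−α/2, df_error)·√(MSE·(1/nᵢ + 1/nⱼ)), at α = 0.01; a pair is
significant only when the omnibus test also passes, which keeps the
familywise type-I error near α under the complete null (the suite measures
≈0.01 over 10,000 seeded null simulations, required within [0.005, 0.02]).
Zero pooled within-group variance is flagged degenerate rather than tested.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of the family it models:
34 candidates (26 genuine + 8 decoys each violating exactly one acceptance
rule, with motif absence guaranteed by rejection sampling), 26 genes on
eight of nine chromosomes (five each on C1 and C5, none on C6), one 2-gene
and two 3-gene tandem clusters with gaps drawn in 15–45 kb and non-cluster
neighbors ≥ 400 kb apart, sub-genome labels 14/10/2, a segmental-block table
covering 13 genes, and per-gene intron-phase plans totalling 54 phase-2
introns (two 7-exon genes carry three each; four genes carry a terminal
phase-1 intron, echoing the IV-b pattern). miRNA bundles implant sites of
exact mismatch/wobble composition (hence known expectation) into random
transcripts, re-scanning to verify background windows stay above the cutoff;
the default 5 miRNAs × 9 genes with 11 sites mirrors the published summary.
Expression bundles draw 19 of 26 expressed rows and Ct tables with known
log₂ folds (noise σ = 0.1, 3 replicates). Codon pairs evolve by proposing
point mutations (0.3 per site by default, 300 codons) and fixing synonymous
changes with probability min(1, 1/ω) and nonsynonymous with min(1, ω).

All randomness flows from one integer seed through per-stage substreams, and
every bundle self-validates against its truth tables before being returned.
Limitations: no indels or rate heterogeneity in the codon process, no
recombination, uniform background composition, protein sequences are random
apart from the implanted motif (so the synthetic family has no real
phylogenetic signal), and FPKM rows are independent lognormals. Passing
tests therefore demonstrate that the *rules and estimators* recover
constructed truth — not that real-genome idiosyncrasies (assembly errors,
alternative isoforms, compositional bias) are handled.

## Problem sizes and reproducibility

The default test and acceptance workloads use 300-codon pairs (50 replicates
per ω for sign recovery), 8-taxon additive matrices, 30-mer peptides for the
pI oracle, and 10,000 null replicates for the LSD calibration — sizes at
which the stochastic guarantees are comfortably separated from their
thresholds while the whole suite runs in well under a minute. The pipeline
writes a manifest (version, seed, parameters) sufficient to reproduce a run
bit-exactly; deterministic stages are byte-identical across reruns.
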