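# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Synthetic communities (`simcom`)

**Sequence model.** Each genome is an order-k Markov chain (default k = 3)
whose per-context base probabilities are independent Dirichlet draws centred
on the GC-consistent composition, with concentration 6. Two consequences are
deliberate: (i) every genome carries *genuine* tetranucleotide structure
beyond what the maximal-order Markov expectation explains, which is what
TETRA z-scores measure — an order-2 chain would make TETRA signatures pure
sampling noise and same-species strains would not reach the 0.99 correlation
a practitioner expects; (ii) the compositional contrast is strong enough that
a ~5-kb fragment of a genome correlates ≈ 0.95 (raw TNF Pearson) with its
genome's mean TNF, the regime in which a 0.90 refinement threshold behaves as
it does on real bacterial contigs. Realized GC is pinned to the target
exactly by a sparse intergenic A/T↔G/C correction pass after ORF planting
(planted ORFs are codon sequences with ~0.5 GC and would otherwise bias
whole-genome GC by up to ~0.01).

**Planted ORFs.** Proteins are reverse-translated with uniformly random
synonymous codons; background proteins use a 19-letter alphabet without
cysteine so that CXXCH motif counts are exact truth by construction.
Cytochromes carry exactly the requested number of C-x-x-C-H motifs at spaced
positions; marker genes are single-copy with IDs from a shared universe;
pilins are built from a fixed synthetic reference mature peptide (61 aa,
labelled synthetic; it stands in for a curated conductive e-pilus) with a
unique class-III leader ending in the only glycine of the precursor, seven
designated essential aromatic columns, a tunable aromatic count, and optional
neutral insertions for indel test cases.

**Strains.** `derive_strain` applies iid per-site substitutions outside ORF
start/stop codons; realized identity is divergence-exact to within binomial
noise (±0.005 at 100 kb). Strain ORF annotations (heme counts, pilin truth)
are re-derived from the mutated sequence, so mutations may genuinely destroy
or create features — that is treated as truth, not error.

**Counts.** Expected DNA count of an ORF (or contig) is
`depth × length / 100` (a nominal 100-bp read). Expected mRNA count is the
ORF's expression level × the genome's *relative* depth in that condition ×
the planted fold change, so expression tracks cell abundance and the
DNA-normalization step has something real to cancel. Noise is `none`
(rounded expectations) or Poisson; no overdispersion is modelled. Default
per-ORF expression levels are lognormal with median ≈ 20 (≈ 200 mRNA reads
for a 1-kb ORF at default depths): at that depth the 5-fold rule is
well-separated from Poisson ratio noise, which is the regime the rule is
meant for; far shallower libraries make the 50-RPKM gate vacuous because
RPKM scales inversely with library size.

**What the generator does not emulate.** Read-level errors and quality,
chimeric contigs, rRNA contamination, inter-genome homology (horizontal
transfer), GC-dependent coverage bias, and overdispersed (non-Poisson)
expression noise. Passing recovery tests therefore demonstrates correctness
of the computational chain under clean community structure, not robustness
to assembly artefacts or biological overdispersion.

## Binning

Features per contig (≥ 500 bp; shorter contigs are excluded): GC,
per-condition mean depth (`count × 100 / length`), and strand-pooled TNF
(forward + reverse-complement counts, normalized; 256 entries with mirrored
mass). Primary clustering is DBSCAN on standardized
`[gc, log10(coverage + 0.1)]` — a mechanization of picking clusters on
coverage-GC and differential-coverage plots; density-based clustering needs
no preset cluster count. `eps` defaults to 2× the median
`min_samples`-th-nearest-neighbour distance (the standard DBSCAN elbow
heuristic) so dense and sparse communities work with one default;
`min_samples = 5`. Noise points stay UNASSIGNED.

TNF refinement demotes a contig whose Pearson correlation to its bin's
length-weighted mean TNF falls below 0.90 (single pass). Linkage rescue
assigns an UNASSIGNED contig to a bin with ≥ 3 summed links and ≥ 2× the
links to any other bin, and re-assigns a contig whose links elsewhere exceed
2× its own bin's; ties go to UNASSIGNED. Both passes run once by default —
determinism and bounded runtime were preferred over fixpoint iteration.

Completeness = % of expected single-copy markers present; contamination =
% of extra marker copies. The marker list is configuration (fixtures define
their own universe). Quality tiers: *high* iff completeness > 90,
contamination < 5, 5S+16S+23S present and ≥ 18 tRNAs; *medium* iff
completeness ≥ 50 and contamination < 10; else *low*. rRNA/tRNA flags are
consumed from an input table — their detection is out of scope.

Community composition: `core_genes` (mean over markers of each bin's
coverage share), `coverage` (length-weighted mean contig coverage,
normalized), `raw_reads` (mapped-read fractions). All include an UNASSIGNED
pool and sum to 1.

## ANIb / TETRA / OCS

ANIb cuts the query into consecutive 1020-bp fragments and aligns each to
the subject by exact 15-mer seeding on both strands followed by ungapped
x-drop extension (match +1, mismatch −2, x-drop 30) from the best-supported
diagonals. A fragment contributes if identity ≥ 30% over ≥ 70% of its
length; ANI is the mean identity of contributors, and the reported value
averages both directions (the threshold applies to that mean). With no
qualifying fragment the result is NA — this is what unrelated genomes
produce, since a chance 15-mer seed extends only a short high-identity
island that fails the 70% coverage filter. On substitution-only strains the
estimator tracks the per-site identity oracle to ≈ ±0.1 over 1–10%
divergence; the small positive bias from trimming mismatch-dense fragment
ends is well inside that. Gapped alignment is not needed for the simulator's
indel-free genomes; the extension is the package's own, and an exhaustive
alignment is used only as a test oracle.

TETRA: tetranucleotide z-scores under the maximal-order Markov expectation
`E[n1n2n3n4] = c(n1n2n3)·c(n2n3n4)/c(n2n3)`, variance
`E·(c2−c3L)(c2−c3R)/c2²`, counts pooled over both strands; zero-variance
words get z = 0. Bins are concatenated with a 10×N separator that
contributes no words. OCS = connected components (single linkage) of the
graph with edges where mean ANIb > 97 **and** TETRA r > 0.99.

Pan-genome detection: inside a multi-member OCS, a candidate core must have
paired-end links to ≥ 2 members and a coverage vector equal to the linked
members' sum within 25% relative L1. Strain-specific contig *clusters* are
emulated as full strain genomes in the simulator; the additive-coverage
criterion is what carries the signal.

## Cytochromes and e-value calibration

CXXCH scanning checks literal C/C/H anchors at every position (overlaps
allowed; ambiguity codes never match anchors). Multi-heme means ≥ 2 motifs:
"multi-heme" semantically requires two hemes and di-/tri-/tetra-heme usage
in the field is consistent with that; the comparator is configurable.
Family assignment is the best gapped local alignment (BLOSUM62, −11/−1)
over the reference set with a Karlin–Altschul-style e-value
`K·m·n·exp(−λS)`. λ = 0.171 and K = 0.0036 were fitted once by
`calibrate_evalue()` — a Gumbel-tail regression on scores of shuffled
random pairs under this exact scoring scheme — and frozen; the e-values are
self-consistent within the package rather than comparable to external
search tools. Ties break by score then lexicographic family ID, logged.

## Expression

RPKM = `C·10⁹/(N·L)` with `L` the ORF nucleotide length and `N` per-sample,
per-molecule-type totals. Normalization divides mRNA-RPKM by
(DNA-RPKM / DNA-RPKM mean over the five conditions): conditions where a
genome is over-represented are corrected *down*, so per-cell expression is
recovered; a flat DNA profile leaves mRNA-RPKM unchanged and a planted 2×
dosage bias cancels exactly. Zero DNA-RPKM yields an undefined (NaN) value
that is excluded downstream, never imputed — expression without evidence of
gene presence is not fabricated. Count tables are the primary input; a
best-hit pseudo-mapper (local alignment, ≥ 0.6 read-length coverage,
≥ 0.95 identity, seeded random tie-split) exists for small read fixtures.

## Response calling and ordinations

A gene is *positive* for a stimulus iff after/before ≥ 5 with after ≥ 50
RPKM, *negative* symmetrically with the gate on the before value
(direction-matched gating); zeros are replaced by ε = 0.01 RPKM before the
ratio, small enough that the 50-RPKM gate always dominates. The open-circuit
stimulus compares con1 vs con4 by default (the late OC sample shares its
substrate background with con1; con3 is available via the design table).

wMDS is SMACOF stress majorization with per-point weights multiplying pair
contributions (w_ij = w_i·w_j), Euclidean distances between per-condition
relative-expression profiles, seeded random initialization; stress is
non-increasing by construction and the iteration stops at Δstress < 1e-10.

wCCA is correspondence-analysis scaling of the gene × condition matrix with
condition scores constrained to the span of the indicator variables:
chi-square standardized residuals are projected onto the weighted, centred
constraint space (pivoted QR) and decomposed by SVD, which is numerically
identical (≤ 1e-16 here) to the dense generalized eigenproblem used as an
independent oracle in the tests, and matches vegan's `cca` on unweighted
inputs. Row weights multiply row masses (weights are normalized first).
Because a complete partition of the five conditions into three indicators
is exactly collinear after weighted centring, aliased columns are dropped
with a warning (vegan's behaviour) instead of erroring — a strict mode
restores the error. Axis signs are fixed by making the largest-magnitude
gene loading positive; biplot scaling type 2 (gene scores scaled by
singular values). Variable arrows are weighted correlations of the
indicator columns with the axes, rescaled to the gene-score cloud so that
midpoint partitioning operates on comparable scales; arrows are reported
for all variables including aliased ones.

Arrow-midpoint partitioning assigns each gene point (first two axes) to the
nearest 0.5× arrow endpoint; points within r0 = 10% of the maximum point
norm of the origin stay unassigned (no radius is prescribed anywhere; 10%
excludes the non-responsive cloud without touching clearly displaced genes).
Ties break lexicographically and are logged.

Marker panels rank KO / cytochrome-family labels by summed normalized
expression (top 50 / top 15 by default; labels are inputs). The heat-map
matrix reports per-label mean mRNA/DNA ratios per condition with a 2-fold
change flag against con1.

## Pilins

Cleavage: earliest G-[FMLIVAS]-x-x-x-E within the first 40 residues, cut
after the G; absent motif ⇒ full-length fallback flagged uncleaved.
Aromatic metrics count F/Y/W/H on the mature peptide (percentages to 1
decimal, computed on the post-maturation length). Essential columns are
checked by global alignment (BLOSUM62, −10/−0.5) to a configured reference;
a reference column aligned to a gap is a miss. Conductivity: *potential
e-pilus* iff aromatic % strictly > 9 and ≥ 7/7 essential hits;
*non-conductive* iff ≤ 9%; otherwise *ambiguous*. Short/long pilin types
split at 80 mature residues (configurable; the field contrasts short and
long PilA without a fixed number).

## Pipeline

`run_pipeline` executes feature extraction → binning → metrics → OCS →
cytochrome annotation → expression → responses → ordinations → pilins on a
fixture directory, writing every table with a header carrying a hash of the
analytic parameters (paths excluded). Identical inputs and config produce
byte-identical outputs; all randomness flows from the single config seed.
Stage thresholds default to: min contig 500 bp, ANI 97, TETRA 0.99, fold 5,
gate 50 RPKM, aromatic 9%, e-value 1e-6, mapping 0.6/0.95.

## Problem sizes

The reference evaluations use: six 420-kb genomes at ~5-kb mean contig
length (~500 contigs) for binning recovery; a 100-kb genome with strains at
1/2/5/10% divergence for ANIb/OCS; 10⁴ random 80-mers for motif-scan
equivalence; 5 000 genes with 50 planted fold-8 responders at ~200-read
baseline for response recovery; 300 genes at 10× effect for partition
recovery; 100 synthetic pilins (a fifth with insertions) for the pilin
chain. Genome and library sizes are scaled to desk-top turnaround while
keeping every estimator in the statistical regime it is designed for.

## Known limitations

Binning assumes compositionally distinct, reasonably covered genomes; very
short contigs (< 2 kb) carry weak TNF signal and rely on linkage rescue.
The ANIb extension is ungapped and will under-cover genuinely indel-rich
homologs. E-values are internally calibrated, not BLAST-comparable. The
wMDS/wCCA weighting scheme (row-mass multiplication) is one defensible
reading of "weighted" ordination; other schemes would shift point
coordinates but not the oracle-checked eigenstructure. The simulator's
clean community structure bounds what recovery tests can claim about messy
real assemblies.
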