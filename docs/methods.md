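# Methods

## The bona-fide LOX decision rule

A candidate locus is accepted into the family only when three pieces of
evidence co-occur on its protein: a PLAT/LH2 domain, a *complete* catalytic
LOX domain, and a correctly spaced 5-histidine signature lying inside the
LOX domain. "Complete" is operationalized as a LOX interval of at least
`min_lox_width` amino acids (default 450, chosen below the smallest
published duckweed LOX interval width, 492 aa, so genuine but short family
members are never rejected while truncated pseudogenes are). Every rejected
candidate records which leg failed: `missing PLAT domain`, `missing or
incomplete LOX domain`, or `missing 5-His signature within LOX domain`.
Removing evidence can only demote a candidate, never promote one.

Domain evidence comes from either (a) a user-supplied interval table — the
practical route for real genomes, where HMMER/InterProScan output is pasted
into a four-column TSV — or (b) the packaged toy profile motifs, used for
synthetic data. The toy motifs are position-frequency matrices scored as
log2-odds against a uniform background, with a hit threshold of 0.6 × the
consensus score. They are not profile HMMs and make no claim of sensitivity
on real proteins; the package's contribution is the decision rule, and the
scanner behind it is swappable.

The 5-His scanner is exact: every 38-aa window with histidine at relative
positions 1, 6, 11, 29 and 38 is reported, overlaps included, spacer
positions unconstrained.

## Subfamily and type assignment

Members are labelled 9-LOX or 13-LOX by highest global-alignment identity
against a labelled reference panel (ties: higher similarity, then
lexicographic reference id). 13-LOX members split into type II (plastid
transit peptide predicted) and type I (none). Because no published
predictor defines the transit-peptide call, a transparent composition
heuristic is used over the N-terminal 60 residues: Ser+Thr fraction ≥ 0.25,
Asp+Glu fraction ≤ 0.08, and (Arg+Lys+His) − (Asp+Glu) ≥ 0. All thresholds
are exposed; proteins shorter than the window are evaluated over their full
length and flagged. This is a structural stand-in, not a validated
targeting predictor.

## Protein properties

Molecular weight sums average (not monoisotopic) residue masses plus one
water, the convention of the standard proteomics calculators. The
isoelectric point bisects the Henderson–Hasselbalch net-charge function on
pH ∈ [0, 14] to |charge| < 1e−4; the charge function is strictly decreasing
in pH so the root is unique and bisection cannot fail. The packaged pKa set
is EMBOSS-style (C-term 3.55, N-term 7.50, D 4.05, E 4.45, C 9.00, Y 10.00,
H 5.98, K 10.00, R 12.00) and swappable; different published constant sets
shift pI by roughly ±0.2 pH units, so comparisons against other tools
should allow ±0.3.

## Alignment and duplication analysis

Pairwise alignment is optimal global Needleman–Wunsch with affine gaps via
Biopython's PairwiseAligner. Defaults mirror the EMBOSS tools: BLOSUM62
with gap open 12 / extend 2 for proteins; match +5 / mismatch −4 with gap
open 16 / extend 4 for nucleotides; a gap of length L costs
open + (L−1)·extend. Identity counts identical unambiguous residues over
the full alignment length; similarity counts positively scoring columns;
ambiguity codes never count as identity. The engine is verified against an
independent exhaustive-enumeration oracle on short sequences.

Intron phases are recomputed from CDS arithmetic — phase of intron *i* is
the cumulative coding length of exons 1..i modulo 3, walking 5′→3′ on the
coding strand — rather than trusted from the stored GFF3 phase column.

Duplication classification follows the standard plant gene-family
convention: per scaffold, genes sorted by start are greedily clustered
while the span stays ≤ 100 kb, the cluster holds ≤ 5 genes, and each added
gene shares ≥ 70% identity with some cluster member (70% sits below the
smallest published duckweed tandem-pair identity, 75.77%, and above
background); clusters of ≥ 2 are tandem arrays. Remaining pairs above 90%
similarity are segmental duplicates; a pair inside one tandem array is
never double-reported. The >90% rule is applied to protein similarity by
default (the published criterion does not specify the sequence type); a
config switch selects nucleotide matrices instead. Intervening non-family
genes are ignored — the rule is a pure coordinate window.

## Phylogeny

Distances use pairwise gap deletion with p-distance or Poisson correction
d = −ln(1 − p) (saturated pairs, p = 1, are an error naming the pair).
Trees are Saitou–Nei neighbor joining with a deterministic lowest-index
tie-break; negative branch-length estimates are clamped to zero and
flagged. NJ recovers any additive matrix exactly, which the tests exploit
as an oracle. Bootstrap supports resample alignment columns with
replacement (default 1000 replicates, seeded) and report the percentage of
replicate trees containing each internal bipartition; supports are
invariant to taxon input order. Likelihood inference is deliberately out of
scope: the contract of the tree stage is topology-level subfamily/clade
display, not branch-length agreement with ML methods. The progressive
aligner adds sequences in NJ-guide order against the running profile's
consensus; it is a desk-scale aligner whose contract is that de-gapping its
output restores the inputs and that clear indels are represented.

## Expression statistics

Quantification follows the Livak 2^−ΔΔCt method. Per sample, ΔCt = target
Ct − arithmetic mean of the reference-gene Cts (two references combined by
Ct mean = geometric mean of quantities). Group ΔΔCt subtracts the control
group's mean ΔCt; the control is either the untreated condition at the
matched timepoint (treatment designs) or a baseline timepoint within each
condition (aging designs). Hypothesis tests run on ΔCt values, which are
approximately normal; folds are reported on the ratio scale. Ct values at
or above the cycle ceiling (default 45) are treated as not expressed and
excluded from statistics, reported separately.

Dunnett many-to-one adjustment is computed by seeded Monte Carlo (default
1e5 draws) of the null maximum |t| with the pooled-variance correlation
structure, rather than closed-form multivariate-t quadrature; adjusted and
unadjusted p-values come from the same draws, so adjusted ≥ unadjusted
holds by construction, and the Monte-Carlo standard error at p ≈ 0.05 is
below 0.001. When each timepoint has its own matched control there is no
shared control group, so the same max-|t| construction is applied with
independent per-comparison controls and a shared pooled variance. The
implementation is cross-checked against an independent closed-form Dunnett
implementation in the tests, and its family-wise error rate is calibrated
by null simulation (0.05 ± 0.02).

Pattern classification is deliberately simple and tie-averse: a
three-timepoint trajectory is monotone-up, peak-mid, monotone-down, or
static (ties → static); a treatment response is upregulated /
downregulated / static / mixed from the signs of significant folds.

## The synthetic data generator

The generator emulates the study design the pipeline targets, with
defaults fixed at those conditions: nine true family members (two 9-LOX,
seven 13-LOX; six of the seven type II), six decoys (default mode: missing
the LOX domain), one two-gene and one three-gene tandem cluster each
within 40 kb, exon counts 4–9 with introns of 80–500 bp, and a qPCR design
of control/treated × (0, 1, 3, 6, 12 h) × 3 replicates against two
reference genes with Gaussian Ct noise of sd 0.2 cycles.

Proteins are built from planted blocks over i.i.d. uniform backgrounds —
the simplest null that keeps false motif hits rare and quantifiable: an
initial Met, an optional transit peptide, the PLAT consensus (100 aa), a
60-aa subfamily archetype block, and the LOX consensus (480 aa) with the
5-His signature embedded. The two archetypes differ at every position, so
distance-based classification has an unambiguous margin. Members mutate at
10% per site, never touching the planted histidines or the transit
peptide; tandem copies mutate independently from their shared ancestral
design at half the configured cluster divergence, so pairwise identity
within a cluster (~90%) matches published tandem pairs while each copy
stays near the domain consensus. Transit peptides use exact shuffled
residue counts (59 aa: 16 S, 9 T, 9 A, 6 L, 6 V, 5 P, 4 R, 4 K) so that,
with the initial Met, the predictor window is satisfied by construction.
Decoys violate exactly their configured mode, and accidental 5-His windows
are disrupted after mutation so the "missing-5His" contract is exact.

CDS sequences use one fixed codon per amino acid plus a TAA stop — the
generator makes no claim to codon usage, repeat structure, or read-level
realism. Genomes, GFF3, proteins, CDS and the ground-truth manifest are
byte-identical for a given seed; every random draw flows from the single
configured seed.

What passing on synthetic data does and does not show: it validates the
decision logic, the coordinate arithmetic, the duplication window rules
and the statistical calibration end to end; it does not validate scanner
sensitivity on real divergent domains, transit-peptide prediction on real
targeting sequences, or alignment parameter choices against real
evolutionary divergence — those require the external genome bundles the
pipeline also accepts.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: 15–17
candidate proteins of ~650–900 aa per bundle, 20 generator seeds for
recall/precision and tandem recovery, 200 simulated qPCR datasets for
fold-change recovery, 1000 null simulations (20 000 Monte-Carlo draws
each) for the Dunnett calibration, and bootstrap replicate counts of
10–100 in tests (the library default stays 1000).

## Known limitations

* Profile scanning is PFM log-odds, not Forward/Viterbi pHMM scoring.
* The transit-peptide heuristic is compositional only and cannot separate
  signal peptides from transit peptides.
* No Ka/Ks dating, synteny/collinearity detection, or
  amplification-efficiency (Pfaffl) correction.
* Trees are distance-based; printed supports on near-degenerate
  alignments are flagged but still reported.
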