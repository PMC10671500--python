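# Methods

This note records the models behind each module, the defaults that
matter, the numerical choices, what the synthetic generators do and do
not emulate, and the known limitations.

## RCL annotation

A serpin's inhibitory competence is read from its hinge, the conserved
P17–P9 stretch immediately N-terminal of the reactive-center loop. The
consensus scored here is P17 [E], P16 [E/K/R], P15 [G], P14 [T/S], P13
wildcard, and P12–P9 each [A/G/S] — eight constrained positions, so a
hinge score is an integer 0–8. The P13 wildcard follows the consensus
notation; whether "P12–9" means exactly four scored positions is an
interpretation, fixed here as four.

**Search window.** The P17 anchor is restricted to `[L − 75, L − 25]`
(L = sequence length): the RCL sits near the C-terminus and typical
serpins are 350–500 aa. Candidates are ranked by score, ties broken
toward the C-terminus (canonical RCL placement). Sequences under 40
residues are rejected as unable to carry an RCL.

**Inhibitory call.** P1 = P17 + 16 and P1′ = P17 + 17 by the fixed
register of the loop. A record is inhibitory when (i) the best hinge
scores ≥ `min_score` (default 6/8 — the literature gives no numeric
cutoff, only "less conserved", so the threshold is configurable), (ii)
at least one residue remains C-terminal of P1, (iii) the P1→C-terminus
tail is ≤ `max_tail` (default 60), and (iv) the P1 residue maps to a
protease class. Note that within the default window the tail is
automatically 10–60 residues, so a long-RCL serpin (tens of residues
inserted into the loop) is caught because its hinge falls N-terminal of
the window rather than by the tail bound; `max_tail` remains as a
safeguard for widened windows.

**Specificity.** P1 → class: R/K trypsin; L/I/Y chymotrypsin, extended
with F/W (large aromatics fit the chymotrypsin S1 pocket); small
hydrophobics A/V/M elastase, extended with G/S. Other residues yield no
class and the record is reported non-inhibitory.

**Physicochemical features.** Mw is the sum of average residue masses
plus one water (18.0153 Da). pI solves net charge = 0 by bisection on
pH ∈ [0, 14] (tolerance 1e-3) under Henderson–Hasselbalch with an
EMBOSS-style pKa table (N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5,
Y 10.1, H 6.5, K 10.8, R 12.5), declared once in `_constants.py`.

**Coordinates.** 1-based inclusive in every user-facing structure;
0-based half-open only inside functions. Signal peptides are input
metadata (ranges like "1–18" or "NO"), never predicted.

**Isoforms.** A gene model is an ordered exon table with one contiguous
slot of mutually exclusive variant exons; each isoform is
shared-prefix + one variant + shared-suffix, so cDNA length is exactly
additive. Translation (standard code, trailing stop stripped, internal
stops rejected) feeds the assembled protein back through the annotator,
which is how isoforms of one gene can differ in P1 and target class.

## Distance phylogenetics

Distances use pairwise deletion: for each pair, p = mismatches over
shared non-gap columns; the Poisson correction d = −ln(1 − p) is the
expected substitutions per site under rate-homogeneous replacement
(p ≥ 1 is a saturation error). Neighbor joining is the Saitou–Nei
agglomeration; pair selection ties break on the lowest index pair, and
negative branch-length estimates are clamped to zero without
redistribution (simplest defensible convention). On additive matrices
the generating topology and lengths are recovered exactly (oracle-tested
against quartet least-squares enumeration and against scikit-bio's NJ).
Bootstrap resamples columns with replacement per replicate; support is
the percentage of replicates whose NJ tree contains each internal
bipartition of the full-data tree, reproducible by seed. Pairwise global
alignment is Needleman–Wunsch via Biopython's `PairwiseAligner`;
identity is matches over all alignment columns including gap columns
(the more conservative denominator; match-column conventions would read
higher).

## Pairwise Ka/Ks

The estimator follows Yang–Nielsen-style counting: κ is estimated from
positions whose codons agree in degeneracy class (fourfold vs
nondegenerate), K2P-corrected per class and averaged by site count
(fallback κ = 2 when inestimable, e.g. identical sequences); synonymous
site opportunity per codon position weights each non-stop mutation by κ
for transitions; substitutions between differing codons average over
equally weighted minimal pathways that avoid stops; pN and pS are
corrected for multiple hits Jukes–Cantor-style. Ka/Ks is flagged
undefined when Ks = 0. NG86 (κ = 1) ships as the cross-check method; on
neutral simulations (ω = 1, κ = 2) the mean estimate is ~0.98 and the
Spearman correlation with NG86 exceeds 0.95. Pairs need ≥ 10 shared
non-gap codon sites. The rank-sum comparison of two groups of ratios
uses full enumeration for combined n ≤ 12 (exact two-sided p) and a
tie-corrected normal approximation otherwise.

## Codon site models

The substitution process is GY94: rate i→j is zero unless the codons
differ at one position, otherwise π_j · κ^[transition] · ω^[nonsyn],
with F3x4 codon frequencies estimated from the alignment
(position-specific nucleotide frequencies floored at 1e-4 so every sense
codon has positive mass). Likelihoods come from Felsenstein pruning over
the 61 sense codons; gap codons are uninformative. Transition matrices
use the reversible symmetrization eigendecomposition, cached per
(ω, κ) within one optimization problem.

Site mixtures: M0 one ω; M3 three free classes (softmax weights); M7 a
beta(p, q) on [0, 1] discretized into 10 equal-probability bins at bin
medians; M8 = p0·beta + p1·(ω_s ≥ 1). Branch lengths are estimated
under M0 (jointly with κ and ω, L-BFGS-B in log space, two starts) and
held fixed for the mixtures. **Rate normalization:** all mixture models
share the M0 mean-rate scale, so the fixed branch lengths keep a single
time unit across models; the nested LRTs compare models fitted under the
same convention. M3's start set includes the M0 solution and M8's
includes the fitted M7 solution (p0 → 1 reduces M8 to M7 exactly), so
the nesting inequalities lnL(M3) ≥ lnL(M0) and lnL(M8) ≥ lnL(M7) hold
after polishing; LRT statistics are clipped at zero. The M7-vs-M8 test
uses df = 2; M0-vs-M3 defaults to df = 4 (three classes add four free
parameters; published tables sometimes print df = 2 for this comparison,
so df is an explicit argument). Bonferroni flags take the family size
(number of clades tested in one run) as an argument.

**BEB.** Positively selected sites are scored by Bayes empirical Bayes:
branch lengths and κ fixed at the M8 estimates, a uniform prior grid of
10 points per dimension over (p0, p, q, ω_s) — p0 at bin midpoints of
(0, 1), p and q log-spaced on [0.1, 16], ω_s at midpoints of (1, 11) —
with each cell's beta component represented by the same 10
equal-probability quantile bins the fitter uses, so the grid model family
is exactly the fitted one. The posterior
probability that a site belongs to the selected class averages over the
grid posterior; PSS means posterior ≥ 0.95. This is a self-contained
implementation of the standard construction, not a numerical clone of
any particular program; grid sizes are configurable constants.

## Gene gain/loss

Family size evolves by a critical linear birth–death process: each gene
duplicates and dies at rate λ (events per gene per My), on a dated
ultrametric tree. The per-gene descendant law after time t is
P(0) = α, P(j ≥ 1) = (1 − α)² α^(j−1) with α = λt/(1 + λt); the i-gene
transition row is its i-fold convolution. The textbook alternating
binomial sum is implemented for scalar queries but the matrix builder
uses the convolution form: the alternating sum loses all precision once
λt > 1 (α > ½), which in testing manifested as a spurious high-λ
likelihood mode. A truncated-generator matrix exponential is available
as the independent cross-check (`method="expm"`), and the two agree to
1e-6 over the oracle grid.

Likelihood is pruning over integer states 0..`max_count` (default 100,
which must be ≥ 2× the largest leaf count) with a uniform root prior on
[1, 2 × max leaf count] — a deliberate, documented simplification of
the conditioning used by dedicated gene-family programs. λ is fitted by
bounded scalar minimization on [1e-6, 0.05] with a boundary flag (e.g.
all-identical counts give λ̂ = 0). Ancestral counts are per-node
max-marginal posteriors from an exact up-down pass (verified against
brute-force state enumeration), with branch deltas child − parent.

**Honest accuracy note.** On the 14-taxon dated fixture tree with
~28-gene families, λ recovery from 200 simulated families is accurate to
a few percent, but *exact* integer recovery of internal counts at
λ = 0.001 is ~50%: with 2λti ≈ 0.5–14 expected events per branch, the
marginal posteriors — although computed exactly and optimal for
exact-match loss — are simply not concentrated enough. Exact ancestral
recovery should not be expected for realistic family sizes on My-scale
trees; the sign of large branch deltas is recovered far more reliably.

## Expression

FPKM matrices (genes × samples, pandas DataFrames) are transformed
elementwise to log2(FPKM + 1). Clustering is average-linkage
agglomerative on either 1 − Pearson (default; groups profile shapes, as
in stage/tissue heatmaps) or Euclidean distance (groups expression
levels), cut to k groups; k is user-supplied (4 for developmental
stages, 3 for tissues in the motivating use case). Group labels are
ordered by descending cluster mean. Constant rows are rejected under the
correlation metric rather than silently given distance 0/undefined.

## Synthetic data

Generators are deterministic functions of (parameters, seed) and return
a `TruthBundle` sufficient to score recovery.

- Proteins: lengths uniform on 345–570 (the typical serpin range),
  uniform residue background (composition realism is not needed by any
  consumer), perfect hinge planted with P17 at 30–70 residues from the
  C-terminus and a P1 drawn from the class mix (R/K, L/I/Y, A/V/M).
  Decoys cycle through a degraded hinge (exactly 3/8 consensus
  positions), a hinge jammed against the C-terminus (RCL-less), and a
  hinge pushed 90–130 residues upstream (over-long RCL).
- Codon alignments: root codons from the equilibrium frequencies,
  per-branch evolution by the exact class transition matrices under the
  same GY94 machinery the fitters use; per-site class/ω recorded.
- Gene counts: branch-by-branch sampling from the BD transition rows,
  internal states recorded.
- Expression: FPKM = 2^(block mean + N(0, sd)) − 1 floored at 0, so the
  log2 transform recovers gaussian blocks exactly. Planted blocks are
  level shifts, so planted-truth tests cluster with Euclidean distance.

What passing these tests shows: the estimators recover what they model.
What they do not show: robustness to alignment error, assembly
artifacts, composition bias, recombination, rate variation across
branches, or RNA-seq count noise — none of which the generators emulate.

## Problem sizes and calibration conditions

The stochastic calibrations run at sizes chosen for a desk machine: the
M7-vs-M8 null calibration uses a 4-taxon tree and 120 codons over 100
replicates (the LRT at the ω_s = 1, p1 = 0 boundary is conservative, so
the measured type-I error sits well under the nominal 5%); planted
positive selection uses a 6-taxon tree with total length ≈ 2.9
substitutions/codon — representative of deeply diverged paralog clades,
where pairwise Ks is commonly above 1 — with 500 codons and 5% of sites
at ω = 5; λ recovery uses 200 simulated families; neutral Ka/Ks uses 50
pairs of 500 codons.

## Known limitations

- JTT/ML protein distances are not implemented (Poisson and p-distance
  only); tree inference is distance NJ, not ML/Bayesian.
- Site models cover M0/M3/M7/M8 with F3x4 and the universal code only;
  no branch or branch-site models.
- The Ka/Ks estimator is counting-based (YN-style), not the full
  ML/model-averaged variants of dedicated calculators.
- The birth–death model is single-λ with no error model on counts and
  no "rapidly evolving family" p-values.
- Signal peptides, genome mining, and multiple-sequence alignment
  quality are out of scope; alignments, trees, metadata and FPKM
  matrices are inputs.
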