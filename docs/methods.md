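# Methods

## Problem and model

`seqppi` is a binary classifier over ordered protein pairs (A, B):
label +1 for an interacting pair, −1 otherwise. The model assumes that
interaction signal is present in sequence composition and short-range
residue context alone — it deliberately uses no structure, homology or
annotation. Two per-protein descriptor families are concatenated per
pair and fed to a Random Forest.

## MMI descriptors

Residues are mapped onto 7 functional groups (C0 = {A,G,V}, C1 = {C},
C2 = {D,E}, C3 = {F,I,L,P}, C4 = {H,N,Q,W}, C5 = {K,R},
C6 = {M,S,T,Y}; side-chain dipole/volume clustering, as in the
Conjoint Triad descriptor). Sliding windows of length 2 and 3 are
typed by the unordered multiset of group codes (28 and 84 types;
enumeration is lexicographic over sorted tuples and frozen — it fixes
the feature order and the TSV headers `mi3_C0C0C0 … f_C6`).

Per type, with all frequencies pseudocounted as
f = (count + 1)/(W + 1) over the W = L − k + 1 windows of width k
(W = L for single categories) and natural logs:

- I(a,b) = f(a,b) ln[f(a,b)/(f(a)f(b))]
- I(a,b,c) = I(a,b) − [H(a|c) − H(a|b,c)], with
  H(a|c) = −(f(a,c)/f(c)) ln(f(a,c)/f(c)) and
  H(a|b,c) = −(f(a,b,c)/f(b,c)) ln(f(a,b,c)/f(b,c)).

The statistics are evaluated on the *single* sequence at hand (one
count vector per protein), not over an ensemble, and the ratios
f(a,c)/f(c) mix denominators (L − 1 + 1 vs L + 1 windows), so they may
exceed 1 and the conditional-"entropy" terms may be negative. This is
intentional: the formulas are implemented exactly as defined, and the
brute-force oracle in the test suite transcribes them independently.
The pseudocount keeps every term finite for any sequence of length
≥ 3.

Two numerical conventions were genuinely open and are fixed as
follows:

- **Role assignment.** The three-way formula is not symmetric under
  permutation of (a, b, c) while a window type is unordered. Default:
  (a, b, c) is the canonically sorted tuple itself. A sensitivity mode
  (`role_mode="average"`) averages the value over the three choices of
  which element plays c (the remaining two, in sorted order, play a
  and b; I(a,b) is a–b symmetric, so the c-choice is what matters).
- **Vector layout.** 84 three-gram terms, then 28 two-gram terms, then
  the 7 pseudocounted group frequencies (pseudocounted for consistency
  with the MI terms, not raw n/L). 119 per protein, 238 per pair.

## NMBAC descriptors

Six physicochemical scales per residue — hydrophobicity, side-chain
volume, polarity, polarizability, solvent-accessible surface area, net
side-chain charge index — are shipped as a plain-text 20×6 table and
z-scored per column. The **population SD** (divide by 20) is the
default: "zero mean, unit SD of the 20 listed values" is then exact to
machine precision; `normalize_properties(ddof=1)` gives the sample
convention if wanted. For scale j and lag 1..lg,

AC(lag, j) = (1/(n − lag)) Σ_{i=1}^{n−lag} X[i,j]·X[i+lag,j].

Defaults: lg = 30 (the accuracy optimum of the lag sweep; the
`lagsweep` command reruns that sweep over {5,…,45}), giving 180 values
plus the 20 raw residue frequencies (no pseudocount — they face no
logarithm) = 200 per protein, 400 per pair. Layout is property-major
(`ac_H_lag1 … ac_NCISC_lag30, freq_A … freq_Y`). Sequences must be
longer than lg; lengths in (lg, 50) are accepted with a warning, since
the 50-residue floor in the curated benchmark sets is a curation rule,
not a formula requirement.

## Classifier

The combined pair vector is [MMI(A) | MMI(B) | NMBAC(A) | NMBAC(B)]
(638 features; MMI block first); `mode="mmi"`/`"nmbac"` select single
families (238/400), `order="BA"` builds the backward vector for
order-sensitivity checks. The Random Forest uses 500 unpruned trees on
bootstrap resamples with 25 candidate features per split ("mtry";
the alternative reading of the split parameter as a minimum node size
is rejected because the forest is explicitly defined by random
variable selection with m ≪ M). Prediction is majority vote; the +1
vote fraction is the ranking score; an exact 0.5 tie resolves to +1
(pinned by test). Everything is seeded: fold shuffling, per-fold
forest seeds (derived deterministically from the run seed, kept below
2³¹), and the synthetic generator.

Cross-validation is stratified k-fold (default k = 5). Plain random
partitioning would also be defensible; stratification was chosen
because it reduces fold-to-fold variance without biasing the mean.
Per-fold reports carry ACC, SN, Spec, PPV, NPV, F-score, MCC and
AUROC/AUPRC computed from the vote fractions, aggregated as
mean ± SD. A metric whose defining ratio has a zero denominator is
flagged undefined (NaN) rather than imputed as 0, and aggregation uses
NaN-aware means so one degenerate fold cannot silently drag averages.
AUROC is the rank statistic (ties half-counted); AUPRC is step-wise
average precision. Pair-input classes partition test pairs by protein
overlap with training pairs: C1 both seen, C2 one, C3 none.

## Synthetic benchmark

The generator emulates *composition-level* interaction signal only.
Negative-class proteins are i.i.d. uniform over the 20 residues.  Each
positive pair draws its own Dirichlet(1) profile over the 7 groups
(spread uniformly within groups) and both partners sample from
(1 − δ)·uniform + δ·profile. Defaults: 500 pairs, balanced labels,
lengths uniform in [50, 500], δ = 0.5, seeded. At δ = 0 positives and
negatives are identically distributed, so chance-level accuracy is the
ground truth; at δ > 0 the planted tilt lives exactly in the group
frequencies the MMI family measures, which makes the MMI-vs-NMBAC
ablation ordering predictable in tests (NMBAC sees it only through
residue frequencies and lag-0-free products, hence more weakly).

What passing these tests shows: the descriptor math is correct, the
pipeline is leak-free and reproducible, and the forest recovers a
planted compositional signal at realistic sample sizes. What it does
not show: performance on real interactomes, where signal includes
homology, domain grammar and network structure that the generator
does not model, and where negatives are constructed, not sampled.

## Run sizes and numerics

The planted-signal evaluation in the test suite and the acceptance
script uses 500 pairs, 5 folds, 500 trees, all three feature modes
plus a δ = 0 null — about a minute on one CPU; the determinism check
repeats a 60-pair run end to end and compares bytes. Descriptor
implementations are vectorized (NumPy window counting / lagged
products) and are verified against loop-level transcriptions of the
defining formulas to 1e−12 on hundreds of random sequences; the
remaining discrepancy is pure floating-point reassociation.

## Limitations

- The conditional-entropy terms are not proper entropies (see above);
  they are features, not information-theoretic estimates.
- Non-standard residues are a hard error by default (`"drop"` opt-in);
  there is no imputation.
- The forest is the only classifier; no hyper-parameter search beyond
  the lag sweep is provided.
- k > 3 windows, other autocorrelation families (Moran, Geary) and
  alternative residue clusterings are out of scope.
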