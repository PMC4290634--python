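# Methods

## Problem and model

O-GlcNAcylation attaches a single N-acetylglucosamine to the hydroxyl
group of a serine or threonine residue of nuclear and cytoplasmic
proteins. The package treats site prediction as binary classification
of the 11-residue sequence window centered on a candidate S/T site
(offsets −5…+5, the site at 0), with the distinctive step that the
positive windows are first decomposed into *substrate motif subgroups*
and each subgroup receives its own classifier.

### Maximal dependence decomposition (MDD)

The decomposition measures statistical dependence between two window
positions A_i and A_j on a 5×5 contingency table of chemically grouped
residues:

    chi2(A_i, A_j) = sum_{m=1..5} sum_{n=1..5} (X_mn − E_mn)^2 / E_mn

where X_mn counts windows with a group-m residue at A_i and a group-n
residue at A_j, and E_mn = X_mR·X_Cn / X is the expected count under
independence. A pair is *significant* when the statistic exceeds the
upper 0.005 critical value for (5−1)(5−1) = 16 degrees of freedom,
34.27 (34.3 to one decimal), recomputed at runtime from the chi-square
inverse survival function.

The five groups are: acidic {D,E}; polar {S,T,G,N,Q,C}; basic {K,R,H};
aromatic {F,W,Y}; hydrophobic {A,V,L,I,P,M}. The memberships of
S, T, G (polar) and P, V, A (hydrophobic) are fixed by the motif
chemistry the method targets; the remaining assignments follow common
chemical classification and are user-overridable.

Recursion: a node holding at least `min_cluster_size` windows is split
at the position i\* with the largest sum of significant chi-square
statistics against all other positions; the split group m\* is the row
with the largest summed chi-square contribution over the significant
partner tables at i\*. Windows with a group-m\* residue at i\* go to
the *present* branch, the rest (including pad/unknown characters) to
*absent*. Recursion stops when a node is too small, no pair is
significant, or a split would empty a branch. Ties break
deterministically (smaller |offset|, upstream before downstream, lower
group index), so trees are exactly reproducible. The center offset is
excluded from dependence computation: its residue is S/T by
construction and the near-degenerate table would distort the choice.

### Feature encodings

Six schemes encode a window (dimensions at n = 5):

| scheme | dim | content |
|--------|-----|---------|
| binary | 220 | one-hot per position, residue order G, A, V, L, I, P, F, M, W, S, T, C, Y, N, Q, D, E, K, R, H |
| aac    | 20  | residue composition over non-pad positions |
| aapc   | 400 | ordered adjacent residue pairs, pad-touching pairs excluded |
| pwm    | 11  | per-offset relative frequency of the window's own symbol in a positive-set matrix with a 21st terminal-signal column |
| pssm   | 400 | PSI-BLAST profile rows of the window pooled by residue type into 20×20, scaled by 1/11, logistic-squashed |
| asa    | 11  | per-residue predicted accessible surface area, min-max normalized over the dataset |

Window termini beyond the protein ends are padded with `-`: pads carry
zeros in the binary and ASA encodings, are excluded from composition
denominators, and own the terminal-signal column of the PWM. Padding
(rather than discarding near-terminal sites) keeps fragment extraction
total on all S/T positions; the PWM's terminal column exists precisely
to represent sequence ends.

ASA normalization is min-max over the whole dataset (a constant column
maps to 0); per-protein normalization was rejected because pooled
training needs cross-protein comparability. Where PSI-BLAST profiles
are unavailable, `fallback_profile` provides per-offset log2-odds of
the positive set over a background (pseudocount 0.01, uniform
background by default) so the PSSM pathway stays exercisable.

### Class balancing and models

Negative windows (all unmodified S/T sites) outnumber positives ~70:1.
K-means with K = number of positives clusters the negative pool on the
binary encoding; each cluster contributes its member nearest the
centroid (ties to the lowest input index; empty clusters refilled from
the grand-centroid neighbourhood). This keeps real sequences, spreads
the negatives over sequence space, and is deterministic under a seed.
Negatives are sampled once globally before fold assignment; a per-fold
re-sampling flag is deliberately not the default because the original
procedure is unstated and global sampling keeps folds comparable.

Classifiers are RBF-kernel SVMs, K(S_i,S_j) = exp(−γ‖S_i−S_j‖²), with
Platt probability outputs and decision threshold 0.5 (probability
exactly 0.5 counts positive). In clustered mode the tree is built on
the training positives, negatives are routed down it by their own
residues, each leaf is balanced to its positive count by a seeded
subsample of its routed negatives (topped up from the global pool if a
leaf attracts too few), and each leaf trains its own SVM. A query
routes to exactly one leaf and uses that model's probability; an
optional stacking SVM over all leaf probabilities exists but is off by
default, since routing is the simplest reading of "combined"
prediction and performed equivalently in our checks.

Hyperparameters come from an exhaustive log2-spaced grid
(C ∈ 2^−5…2^15, γ ∈ 2^−15…2^3, steps of 2 in the exponent) maximizing
cross-validated balanced accuracy (Sn+Sp)/2, a natural objective when
the goal is high sensitivity and specificity at the same time; the
grid extent and objective are this package's own choices. Ties prefer
smaller C, then smaller γ.

### Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, and the
Matthews correlation coefficient. Metrics with zero denominators are
reported as NaN, never as 0. Cross-validation is stratified 5-fold
(stratification keeps the class ratio near-constant across folds,
which matters under imbalance), confusion counts pooled over folds
before computing metrics, and fully seeded. Independent evaluation
runs at the test set's natural class ratio and warns (listing
offenders) if any test site coincides with a training (protein,
position) pair.

## Synthetic benchmark

The generator emulates positional residue composition only: i.i.d.
background residues (uniform 1/20 by default, a Swiss-Prot-like table
ships as an alternative; uniform keeps chi-square nulls clean), no
homology, no domain structure, no realistic length distribution.
Passing tests on it demonstrate that the algorithms recover planted
positional structure at realistic sample sizes — not performance on
real proteomes.

Default study conditions mirror the real training scale: 3 motif
classes × 125 positives = 375 sites on 100 proteins of length 500.
Each class *enriches* its anchor — polar S/T/G at +4, polar S/T/G at
+1, hydrophobic P/V/A at −3, with probability p_e = 0.9 — and
*depletes* the other two classes' anchor groups at their positions
with the same probability (the residue is overwritten by a draw from
the group's complement). The depletion mirrors the
enrichment/depletion asymmetry that two-sample logos show in real
substrate data, and it is what makes the anchor positions mutually
dependent: a mixture of purely single-position enrichments yields
pairwise chi-square values of roughly 12–28 at N = 375, mostly below
the 34.3 threshold, and is not reliably decomposable by any
dependence-based method at this sample size. Planted windows never
overlap and keep a full margin from protein termini.

Benchmark problem sizes (the package's own choices for desk-scale
studies): the negative pool is capped at 8× the positives for the
K-means step, and the direction study picks (C, γ) from a reduced
four-point grid once per dataset, shared by both model modes so the
comparison isolates the effect of the clustering itself. Observed
behaviour over 20 seeds: motif recovery 20/20 (a leaf's *dominant
signature* — the (offset, group) with the largest one-proportion
z-score against background — matches each planted anchor); null
significant-pair rate statistically consistent with the nominal 0.005
level; clustered mean balanced accuracy ≈ 0.72 vs single ≈ 0.67, with
clustered ≥ single in 20/20 seeds. These numbers are recomputed by
`scripts/acceptance.py` and the test suite, not asserted as constants.

The companion fixtures are explicitly synthetic: ASA values are
uniform draws damped 30% inside positive windows (emulating the lower
solvent exposure reported around modified sites), and the per-protein
"PSSM" files score the native residue +4, others −1, plus the
positive-set log-odds inside planted windows.

## Numerical and degenerate-input choices

- Chi-square cells with E_mn = 0 contribute 0 (their observed count is
  forced to 0; avoids 0/0).
- A split that routes every window to one branch is treated as no
  split, preventing infinite recursion.
- Characters outside the 20-letter alphabet are mapped to `X` on read
  (logged, never dropped) so positions stay stable; `X` carries no
  chemical group, no one-hot bit, and is excluded from tallies.
- Position conventions: 1-based in all external files, offsets −n…+n
  with the site at 0, 0-based internally.
- Undefined metrics are NaN; presentation rounds to 2 decimals but
  machine output keeps full precision.
- All randomness (generator, K-means, fold shuffling, subsampling,
  Platt scaling) flows from explicit integer seeds; identical
  configuration reproduces byte-identical trees, bundles, metrics and
  predictions.

## Known limitations

- The AAC/AAPC/PWM reading is window-level (composition "in a sequence
  fragment"); whole-protein composition variants are out of scope.
- Site records for residues other than S/T are rejected: the method is
  defined only for serine/threonine.
- The package does not run PSI-BLAST or any ASA predictor; it reads
  their outputs (and provides synthetic stand-ins for testing).
- MCC values on balanced designs are reported as computed; no attempt
  is made to reproduce published MCC figures whose underlying class
  ratio is ambiguous.
- Real-data performance claims require the original external datasets,
  which the package deliberately does not fetch.
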