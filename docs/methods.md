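# Methods

## Statistical model

All statistics operate on logged abundances. For a conditions × genes
matrix of strictly positive values, write `A_i = log(s X_i)` for the
logged absolute amount of gene *i* and `Y_i = log(X_i / X_d) = A_i − A_d`
for its additive log-ratio (alr) transform against reference gene *d*;
the centred log-ratio (clr) uses the per-condition geometric mean as the
reference instead. The package treats columns as samples of scalar
random variables and works throughout with *sample* moments
(denominator `n − 1`; the sources are silent on the denominator, so this
convention is stated rather than assumed known, and it cancels from every
ratio-type statistic). Natural logarithms are used everywhere; the base
cancels in ρ, φ, correlations and all distortion formulas, but not in a
raw log-ratio variance, which is therefore reported in natural-log² units.

The measured quantities per pair are

- `vlr = var(A_i − A_j)` — zero iff the pair is exactly proportional;
- `ρ = 2 cov / (var_i + var_j)` — symmetric, range [−1, 1], −1 for
  reciprocal pairs; equal to `1 − vlr/(var_i + var_j)`, to
  `2r/(β + 1/β)`, and to `(1 − β̃²)/(1 + β̃²)` with
  `β̃² = var(A_i − A_j)/var(A_i + A_j)`;
- `φ = vlr / var_i` — asymmetric; the all-pairs table fixes the
  orientation to the row gene's variance in the denominator (swap the
  pair to get the other orientation);
- `β = sqrt(var_j / var_i)` (positive root; the sign of the association
  lives in `r`).

### Reference distortion

The exact effect of the reference is captured by one scalar per pair,

```
F = varphi² − 2 sqrt(1 + ρ_abs) · corr(A_i + A_j, A_d) · varphi,
varphi² = 4 var(A_d) / (var_i + var_j) = 1 / (2C),
```

where `C = (var_i + var_j) / (2 var(A_d))` is the pair-average-to-
reference variance ratio,

through `ρ(Y) − ρ(A) = (1 − ρ_abs)/(1 + 2/F)`. This is an algebraic
identity of (co)variances, so it holds for sample moments exactly, not
just asymptotically — the empirical convergence tests at n = 10⁴ are
checks of the implementation path (simulation → transform → ρ), not of a
limit theorem. For realizable configurations F ≥ −(1 + ρ_abs) > −2, so
the pole of the relation at F = −2 is never reached from data; it is
still guarded by an explicit `PoleError` (and masked in sweeps) because
the function itself is exposed for arbitrary arguments.

Derived machinery, all at a cut-off `K` on ρ:

- small-reference expansion of ρ(Y) in `varphi` to first or second order
  (remainder is cubic; verified empirically with a log-log slope check);
- worst-case cut-off adjustment `ρ(Y) ≤ ρ_abs + varphi ·
  sqrt((1 − ρ_abs²)(1 − ρ_abs))`; at the conventional working point
  ρ_abs = 0.98 the coefficient is 1/35.53, exposed both exactly and with
  the conventional rounded divisor 35;
- regime classification: with `K̃ = 2(K − ρ_abs)/(1 − K)`, the pair is
  called on the relative data iff `F ≥ K̃`, giving the TP/FP/TN/FN
  quadrants directly from (F, K, ρ_abs);
- spurious-proportionality threshold for unchanged genes: pairs whose
  individual variances stay below `var(ε)` and whose ρ_abs < K are all
  called once `var(A_d) ≥ 8 var(ε)/(1 − K)`. This is a *sufficient*
  threshold; no tightness claim is made or tested (a much smaller
  reference variance demonstrably leaves non-called configurations).

Admissibility of a scalar configuration (ρ_abs, variances, corr with the
reference) is defined as positive semidefiniteness of the implied 3×3
covariance of (A_i, A_j, A_d), with the reference covariance split evenly
between the two genes (only the sum enters any formula, so the split is
immaterial). Grid searches skip inadmissible points.

### Partial proportionality

`partial_rho` is ρ evaluated on the residuals of the pair after
least-squares regression (with intercept) on a single third gene.  Three
closed forms in pairwise moments are computed and cross-checked against
each other at every call (guard 1e-6; the test suite requires 1e-10 on
nondegenerate inputs) and against an independent brute-force
regression-residual oracle in the tests.  Degeneracy policy: collinearity
of the covariate with *one* member is allowed (the coefficient is then 0,
which is the informative answer); an error is raised only when the
covariate absorbs both members (residual variance below 1e-14 of the
input variance) or is itself constant.  Partialling on more than one gene
is out of scope.

## Transforms and data handling

Matrices are conditions × genes (a transpose flag is the reader's job at
I/O time, not a hidden heuristic). Transforms refuse zeros; a pseudocount
is explicit, caller-chosen and recorded in metadata — there is no default
value, because any default silently changes every low-count ratio.
The clr geometric mean is computed as the mean of logs. alr keeps the
original gene order minus the reference and stores the reference
identity; a supplied-normalizer variant implements the
normalization-as-backtransform view (subtracting the log of a
per-condition factor is itself an alr), which is also how the synthetic
round-trip test recovers absolute data from closed data using the true
`log s`. On-disk format is plain TSV/CSV with a condition-id column and
gene-id header, written at 17 significant digits so round trips are
lossless at double precision.

## Synthetic data generator

The generator is log-normal: every structure is specified on the log
scale, where all the package's statistics live, and exponentiated once.
It produces (i) blocks of proportional genes — a shared latent profile
per block plus per-gene offsets and within-block noise; a non-unit block
slope turns proportionality into a power law and exercises β ≠ 1;
(ii) an unchanged set with small log-sd `eps_sd`; (iii) free background
genes; and (iv) a per-condition trend that block and free genes couple
to, so the total `s = Σ exp(A)` follows the trend and closure transfers
its variance into every gene. Ground-truth pair labels are computed from
the *realized* matrix at the stated cut-off, never from the generative
intent, so confusion analyses downstream are exact.

`trend_scenario` fixes the study conditions used by the end-to-end
evaluation: 16 conditions and 300 genes (six blocks of ten, twenty
unchanged genes, the rest free), a linear decline with trend variance
≈ 0.45, and unchanged genes with absolute log-variance ≈ 0.014 composed
of `eps_sd = 0.06` noise plus a small anti-trend coupling (−0.15). The
variance figures mirror the reported behaviour of real fission-yeast
quiescence data (total-mRNA log-variance 0.45; unchanged-reference
variance 0.014); the anti-trend tilt reproduces the empirically observed
property that a good housekeeping reference ends up negatively
correlated with the changing pairs — which, by the monotonicity of the
distortion in the reference correlation, is precisely what makes the
zero-false-negative outcome structural rather than a sampling accident.
Within-block noise (0.09) puts realized block-pair ρ near 0.99, dense
enough around the 0.98 cut-off to make the comparison non-trivial.
The evaluation runs 20 seeds; with these sizes the whole scenario
(3 × ~45 000-pair tables per seed) takes a few seconds per seed.

What the generator does **not** emulate: count noise (Poisson/negative
binomial), zeros and dropout, library-preparation artefacts, or any
mean–variance relationship — abundances are smooth log-normal. Passing
tests therefore demonstrate the behaviour of the *statistics and the
reference theory* under the assumed second-moment structure, not
robustness of the pipeline to sequencing noise models.

`plant_reference` appends a reference gene whose logged values hit a
target sample variance and sample correlation with a designated pair sum
*exactly* (Gram–Schmidt construction), which is what lets the exact
distortion relation be probed at chosen F on finite data.

## Numerical and interface choices

- ρ clamps floating-point overshoot beyond ±1 within 1e-12 and raises
  beyond that; identity property tests run at 1e-10.
- Degenerate inputs raise typed errors rather than returning sentinels,
  with one documented exception: `var(a_i + a_j) = 0` (exact
  reciprocality) reports `β̃ = ∞` with ρ = −1.
- Thresholds are inclusive: ρ ≥ K, φ ≤ K. The full-specificity cut-off
  is the max (for ρ; min for φ) of the relative statistic over false
  positives and is an *exclusive* bound: any cut-off strictly above
  (below) it yields zero FP.
- Reference auto-selection minimizes the coefficient of variation of the
  unlogged expression, on absolute-scale data; on closed data the CV
  reflects the closure shift, so the call is allowed but warned. Ties
  break lexicographically (logged). The selection report includes
  per-condition expression of the top candidates because condition bias
  has no formula — it is an inspection step.
- All-pairs tables are computed from the gene–gene covariance matrix in
  one vectorized pass; zero-variance genes are excluded and listed in the
  table's metadata. Pair universes are keyed by sorted gene-id pairs so
  absolute and relative tables align regardless of column order.
- CLI exit codes: 0 success, 2 input/parameter errors, 3 degenerate-data
  errors.

## Known limitations

- The theory module's scalar interface describes one pair at a time; no
  multiplicity control is provided or intended (the method uses fixed
  high cut-offs, not p-values).
- The isometric log-ratio transform, Lin's concordance with intercept,
  regularized partial-correlation networks and quantile normalization
  are deliberately out of scope.
- Corollary-type statements are verified numerically over grids, not
  proved symbolically.
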