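# Methods note

This note records the statistical model, the default parameters and why
they were chosen, what the synthetic-data generator does and does not
emulate, the numerical choices, and known limitations.

## Estimators

### SparCC correlation

Input is a samples × taxa table. Count tables (or relative tables with
zeros) receive a pseudocount (default 0.5) and are renormalised. For
positive relative abundances x, the pairwise log-ratio variance

```
t_ij = Var_k[ log(x_i^(k) / x_j^(k)) ]        (population variance, / S)
```

is normalisation-invariant. Under the sparsity assumption the basis
log-variances solve

```
omega_i^2 = b (a + 1) sum_j t_ij - b sum_ij t_ij,
a = 2D - 3,  b = 1 / (2 (D - 1)(D - 2)),
```

and the correlation is `rho_ij = (omega_i^2 + omega_j^2 - t_ij) /
(2 omega_i omega_j)`, clipped to [-1, 1] for reporting. D >= 4 is required
for the closed form to be meaningful. The classical iterative
strong-pair-exclusion refinement is deliberately omitted: the estimator is
the one-pass analytic solution, which is what the per-sample decomposition
below decomposes exactly.

**Negative variance estimates.** When the sparsity assumption is badly
violated the closed form can yield `omega_i^2 <= 0`. The value is floored
at 1e-12 (with a `RuntimeWarning`) *inside the square roots only*; the
numerator keeps the raw closed-form value. This keeps the decomposition
identity exact in all cases while keeping the denominator real. Clipped
correlations for such taxa are saturated and should not be interpreted
quantitatively.

### Single-sample networks (SSN)

With centred log abundances `z` (S × D), `d_ij^(k) = (z_i^(k) - z_j^(k))^2`
and per-sample row/total sums of `d`, the per-sample correlation slice is

```
rho_ij^(k) = [ b (a+1)(row_i^(k) + row_j^(k)) - 2 b tot^(k) - d_ij^(k) ]
             / (2 S omega_i omega_j),
```

which satisfies `sum_k rho^(k) = rho` (unclipped) exactly — verified in the
tests to ~1e-15. Means and basis variances come from the full cohort (no
leave-one-out), so a sample equal to the cohort mean contributes a zero
slice. Edges are pairs with `|rho_ij^(k)|` above a magnitude threshold tau,
or alternatively the top-q fraction of pairs (lexicographic tie-break).
The default tau is chosen so the *median* SSN density across samples is 10%
of the D(D-1)/2 candidate pairs — dense enough that typical samples have a
non-trivial network, sparse enough that edge counts vary between samples.

### Co-abundance groups (CAG)

Edge significance uses permutation pseudo p-values by default: each
replicate independently shuffles every taxon column, destroying all
between-taxon association while preserving margins;
`p = (count + 1) / (n_boot + 1)` with floor `1/(n_boot + 1)`. A bootstrap
sign-stability mode is available behind a flag. Edges require `rho > 0.4`
and `p < 0.05` (positive co-abundance only by default; an absolute-value
flag exists). Clusters are connected components refined by average-linkage
(distance `1 - rho`, cut at `1 - r_thresh`) applied to components of at
least 3 taxa; singletons are kept as their own groups. The defaults
(0.4 / 0.05 / 100 replicates) are the conventional operating point for
moderate cohort sizes; 100 replicates bounds the attainable p at ~0.01,
which is adequate for a 0.05 threshold.

### Co-occurrence networks, hubs, robustness

CAG-abundance networks use Spearman correlation with unadjusted p < 0.05
(edge signs from rho). For S < 10 without ties the permutation null is
computed exactly by enumeration; otherwise the asymptotic approximation is
used. Hubs are nodes whose degree share exceeds 4% of total degree. Degree
distributions are summarised on log-log axes without a formal power-law
fit (networks here are far too small for one). Robustness is

```
R = (1/N) sum_i sigma(i/N),
```

where `sigma` is the across-replicate pointwise median of the largest
connected component fraction after each random node removal, estimated by
reverse percolation with a union-find structure (O(N + E) per replicate,
default 1000 replicates). A complete graph attains the maximum
`R = (N-1)/(2N)` exactly; a single node gives 0.

### Responder analysis

Responders are subjects with `hfc_change < -5` strictly (percentage points
of hepatic fat, followup minus baseline). SSN edge weights form a
D(D-1)/2-column feature matrix (lexicographic pair order). Evaluation is
twofold: (i) *unsupervised* ROC of a single network attribute used directly
as a score (orientation reported, never tuned); (ii) penalized regression
(elastic net with l1_ratio 0.5 by default, or lasso) of the
post-intervention HFC level, with internal standardization,
cross-validated regularization (leave-one-out by default — cohorts are
small), and held-out predictions via cross-validation; predicted change =
prediction - baseline, passed through the -5 rule to obtain predicted
labels and ROC curves (both resubstitution and held-out are reported;
trust the held-out one).

## Synthetic data

The generator draws latent log abundances from a multivariate normal
(`log_mean` spread over 2 natural-log units by default, unit log-SD),
exponentiates, normalises (softmax), and samples multinomial counts at
fixed depth (default 10,000, a typical 16S library size). Correlation
structure is planted as explicit pairs or equicorrelated blocks. The
cohort generator adds a latent connectivity score `s ~ N(0,1)` per subject
that (a) scales that subject's abundance deviations by `exp(0.5 s)` and (b)
drives `hfc_change = c0 - effect * s + noise * eps`, with the intercept
placed so the expected responder fraction hits its target (default 0.5).
Defaults `effect = 4`, `noise = 4` give a signal-to-noise ratio of 1 —
strong enough to be detectable in a 20-subject cohort, weak enough that
detection is not trivial. All defaults were fixed a priori from these
design considerations.

What it **does** emulate: compositionality, multinomial sampling noise at
realistic depth, planted correlation structure, and an outcome coupled to
network connectivity.

What it does **not** emulate: zero inflation beyond multinomial sampling,
overdispersion (no Dirichlet layer), phylogenetic correlation structure,
longitudinal within-subject dependence, batch effects, or realistic
taxon-abundance distributions (no fit to real data).

## Numerical choices

- Population variances (divide by S) throughout; the 1/S prefactor in the
  SSN slices matches this convention and is what makes the decomposition
  identity exact.
- Basis-variance floor 1e-12 inside square roots only (see above).
- Covariance matrices built from planted pairs are checked for positive
  semi-definiteness; eigenvalues are clipped at 1e-8 × (max eigenvalue) and
  the matrix rescaled if the violation is mild (shift <= 10% of the largest
  eigenvalue, with a warning), otherwise rejected with an error.
- Multivariate normal sampling uses the Cholesky path (hence the strictly
  positive eigenvalue floor).
- Lexicographic tie-breaks make edge selection and feature order
  deterministic.
- All stochastic routines take explicit integer seeds.

## Limitations

- The sparsity assumption fails for small D or strongly co-varying
  communities; floored basis variances are the symptom, and correlations
  involving those taxa are unreliable.
- The one-pass estimator is biased relative to the iterative refinement
  when a few very strong pairs dominate.
- Spearman edge p-values are not multiplicity-adjusted (by design, matching
  common practice for small CAG networks); interpret network-level
  statistics, not individual edges.
- Unsupervised ROC on a chosen attribute is descriptive; with small cohorts
  its variance is large.
- Penalized-regression feature selection on D(D-1)/2 >> S features is
  unstable; selected edges should be treated as candidates, not findings.
- The synthetic cohort couples outcome to a *global* connectivity score;
  it cannot validate methods that localise effects to specific taxa.
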