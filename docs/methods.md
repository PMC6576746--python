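# Methods

## One-class factorization with structure-screen imputation

The solver treats drug-target interaction prediction as weighted one-class
matrix completion. Every cell of the chemicals x proteins grid enters the
least-squares term, with a class-dependent confidence weight:

| cell class            | target value            | weight (default) |
|-----------------------|--------------------------|------------------|
| observed in `R`       | recorded value (1)       | `w_obs` = 1.0    |
| imputed in `Q`        | imputed value (1.0)      | `w_imp` = 0.5    |
| everything else       | 0 (or uniform value)     | `w_zero` = 0.01  |

The invariant `w_obs >= w_imp >= w_zero >= 0` encodes decreasing trust:
assayed positives, then structure-derived putative positives, then the
unknown background. The background is never materialized — all dense
contractions reduce to rank-r Gram products plus sparse corrections, the
standard implicit-feedback algebra.

Two imputation modes exist. *Structure mode* places explicit `Q` entries
(default value 1.0, weight 0.5) at pairs passing the dual-threshold
screen; the value/weight split says "treat these as putative positives,
but with half the influence of an assayed one". *Uniform mode* is the
no-structure baseline: a single scalar (default 0.1) imputed implicitly
into every unobserved cell. The two agree by construction when every pair
passes the screen and values match.

Graph regularization adds `beta * tr(U'(D_C - C)U)` and the analogous
protein term: a Laplacian smoothness penalty equal to
`0.5 * sum_ij S_ij ||row_i - row_j||^2`, forcing similar chemicals
(proteins) toward similar factors so that information flows to rows and
columns with few observations.

### Optimization

The update rules are multiplicative, obtained by splitting the gradient
into nonnegative parts (the graph-regularized weighted NMF scheme):

    U <- U * [ (W.M)V + beta C U ] / [ (W.P)V + alpha U + beta D_C U ]

with `P = UV'`, elementwise product/division, and a `1e-12` floor in the
denominator. This preserves nonnegativity and decreases the objective at
every half-step; the recorded objective history is asserted non-increasing
(1e-9 relative slack for round-off) in the tests. Iteration stops when
the relative objective change falls below `tol` (default 1e-6) or at
`max_iter` (default 500, with a warning). Fits are bitwise reproducible
for a fixed seed.

Initialization is uniform random in `[0.1, 1] * sqrt(mean(R)/r)`, seeded.
A behavior worth knowing: from *small* random initializations,
multiplicative updates act like power iteration and can align all
components with the dominant direction before the data can separate them.
The chosen scale avoids this in all tested regimes; if factors collapse
(all singular values of `P` but one near zero), suspect an overly strong
graph penalty first (next paragraph) rather than the initialization.

### Choosing `beta`/`gamma`: a scaling argument

The Eq-style penalty uses the *unnormalized* Laplacian, whose magnitude
grows with graph degree: a node with degree `d` feels a pull of order
`beta * d` toward its neighbors' mean, competing with a data pull of
order `w_obs * (entries in its row)`. The function defaults
(`beta = gamma = 0.1`) are appropriate for genome-scale similarity
networks, which are extremely sparse (typical degree well below 1). For
dense similarity graphs — such as the cosine graphs of the synthetic
benchmark, with typical degree in the tens — `beta` must shrink
proportionally or the penalty dominates and drives the factors toward the
graph-constant (rank-one) solution. The benchmark harness
(`holdout_auc`) therefore uses `beta = gamma = 0.01`; at that setting the
graph terms measurably help (held-out AUC ~0.996 vs ~0.989 with graphs
off on the default benchmark), while 0.1 collapses the fit. A
degree-normalized Laplacian would remove this sensitivity but would
change the stated objective, so it was not adopted.

### Hyperparameters

| parameter | default | meaning |
|-----------|---------|---------|
| `rank` r  | 100     | latent dimension; use ~ the expected number of interaction communities (the synthetic benchmark uses its true rank 5) |
| `alpha`   | 0.1     | Frobenius shrinkage on both factors |
| `beta`, `gamma` | 0.1 | graph-penalty strengths (see scaling argument) |
| `tol`     | 1e-6    | relative objective-change stopping rule |
| `max_iter`| 500     | iteration cap |

## Activity standardization

Potency cut-offs: IC50 <= 10 µM, Ki <= 5 µM, pKi >= 5 (boundaries
inclusive, as the inequalities are stated); note pKi >= 5 equals
Ki <= 10 µM on the molar scale, a deliberately looser rule than the µM-Ki
one. Percent inhibition at concentration `c` converts by
`Ki = c (100 - pct)/pct` and is then judged by the 5 µM rule; 0%
inhibition is inactive (the conversion diverges), 100% gives Ki = 0.
Records carrying a curation confidence below 9 are dropped; records
without a confidence score are kept. Conflicting calls across sources
resolve to *active* (logical OR), consistent with the one-class reading
of `R` as accumulated positive evidence; an AND or majority rule would
instead encode distrust of single sources, which the downstream weights
already express. All concentration-like values are µM internally.

## Structure screen

A candidate (drug, protein) pair survives when the binding-site
similarity p-value is < 2.0e-3 and the docking score < -7.5 kcal/mol,
both strict, matching the stated "less than" rules. When several
structures map to one accession, the best evidence per pair is kept
(minimum p-value, most negative score) before thresholding. Docking
records without a site hit are ignored (logged), since the screen's logic
is "similar pocket, then plausible pose". Survivors form `Q`; pairs
already observed in `R` are dropped so `Q` and `R` stay disjoint.

## Dose-response models

*Binding*: `response = background + (signal - background)/(1 + dose/Kd)`,
the single-site competition form with Hill slope fixed at 1 — the
response falls from `signal` at zero dose to `background` at saturation
with midpoint at Kd. The printed source formula's denominator is
ambiguous as typeset; this reading (`dose/Kd`) is the one consistent with
a response that *decreases* with dose, and is recorded here as an
interpretation. Fits use Levenberg-Marquardt with the deterministic
initialization background = min(y), signal = max(y), Kd = geometric mean
dose.

*Viability*: the four-parameter logistic `y = A + (B-A)/(1 + (C/x)^D)`;
`C` is optimized on the log scale so it stays positive, and the initial
slope sign follows the observed response direction (a falling viability
curve fits with `D < 0` in this parameterization). Constant-response
input is rejected as degenerate.

Derived potency values invert the fitted closed form analytically
(`x = C ((L-A)/(B-L))^(1/D)` for level `L`), never root-find on data:

* EC50 = the fitted midpoint `C`;
* IC50 solves `y = B/2` — "half the maximum possible response" read as
  half the upper limit, flagged as an interpretation;
* GI50 solves `y = (B + time_zero_count)/2`, the level midway between
  the curve maximum and the cell count at compound addition; reported as
  not-reached (None) when the level lies outside the asymptote range and
  flagged degenerate when it coincides with the maximum (tolerance 1e-6
  of the response range).

Activity area is the discrete sum over tested concentrations of
`clip(1 - y, 0, 1)`, giving the range [0, n] for an n-point series
(0 = no inhibition anywhere, 10 = complete inhibition on the standard
10-point half-log series from 100 µM). Whether a given assay vendor's
"activity area" matches this clipped-sum convention exactly is not
verifiable from printed summaries, so no packaged number is asserted
against it.

## Sensitivity genomics

Cell lines: sensitive (activity area >= 1.95), resistant (<= 1.3),
intermediate otherwise; intermediates are excluded from testing. Per gene,
a classical pooled-variance two-sided Student t-test (not Welch) compares
log2 expression between groups; zero-pooled-variance genes get
t = +/-inf, p = 0 when the means differ and t = 0, p = 1 otherwise.

Fold change is the *ratio of mean log2 levels*, sign-flipped toward the
larger group, with FC = 1 at a tie. This ratio-of-logs form is
non-standard (a conventional log-difference would be `E_S - E_R`) but is
implemented as specified; genes whose applicable denominator is
non-positive are flagged rather than given a value.

The q-value is `q_i = (p_i / rank_i) * N` with ascending average ranks —
the first step of Benjamini-Hochberg *without* the step-up monotonicity
pass, so q need not be monotone in p and can exceed the BH-adjusted
value; this divergence is deliberate and documented. Genes with
q < 1e-3 (strict) split into sensitivity/resistance sets by fold-change
sign.

Over-representation uses the exact hypergeometric upper tail per term,
fold enrichment `(k/n)/(K/N)`, Bonferroni `min(1, p*m)`, and a Benjamini
column computed with the same rank-based q formula. It is a generic ORA:
its numbers depend on the annotation collection supplied and are not
comparable to any external tool's output on different ontology versions.

## Kinome-panel evaluation

Truth: a kinase is a real off-target when %control at the high dose is
strictly below 30.0. Predictions: the top `k = ceil(fraction * panel)` of
the ranked list (2.5% of a 452-kinase panel gives k = 12). Metrics are
percent precision, recall and FPR from the 2x2 table, reported at 3
significant figures for display; a zero denominator reports 0, matching
the convention of published tables that print 0 for methods with no true
positives.

## Synthetic generators: what they do and do not show

`simulate_interaction_data` plants block-structured nonnegative factors
(5 blocks at the default rank 5; each row has one dominant block loading
plus uniform noise), takes the top 5% of the product's cells as true
positives, hides 20% of them (half revealed to `Q` as the "structure
screen", half kept for evaluation), and builds C/T as cosine similarity
graphs of the true factor rows (entries below 0.05 dropped, zero
diagonal). The defaults — 200 chemicals x 100 proteins, seed 42 — are
chosen so a fit takes under a second and the whole suite stays in tens of
seconds. Passing the held-out-AUC harness on this generator shows the
solver exploits low-rank structure and informative similarity graphs; it
does **not** show robustness to assay noise heterogeneity, database
redundancy (near-duplicate compound series), hub proteins, or
similarity graphs that are only weakly related to binding — all present
in real chemical-genomics data.

`simulate_dose_response` adds i.i.d. Gaussian noise to the closed-form
curves (no heteroscedasticity, no plate effects). `simulate_expression`
draws log2 levels from Normal(8, 1) with a planted mean shift in DE genes
(no correlation structure between genes). Noise levels in tests (sd 2 on
a 0-100 binding signal; effect size 0 for null calibration) were fixed
with the generators.

## Numerical choices and degenerate inputs

* Multiplicative-update denominator floor: 1e-12.
* Similarity matrices are symmetrized as `(S + S')/2` (warning when the
  asymmetry exceeds 1e-8) and self-loops removed before Laplacian
  construction; entries must lie in [0, 1].
* Ranking ties break by protein index order (stable sort).
* Empty `R` and `Q` collapse the factors to zero with objective zero.
* `R`/`Q` overlap at any cell is an error, not a silent merge.
* Index order in assembled matrices is lexicographic, making
  construction deterministic; duplicate pair records collapse (max value
  in valued mode).

## Known limitations

* The multiplicative solver converges linearly; high-precision planted
  recovery (relative error < 1e-3) needs thousands of iterations. The
  planted-recovery test runs ~5000 iterations (~15 s); an ALS/HALS
  backend would be faster but would not change the fitted optimum.
* `fit_sigmoid` uses unconstrained Levenberg-Marquardt on (A, B, log C,
  D); pathological curves (non-monotone, saturated at one asymptote) can
  fail to converge and raise rather than return a poor fit.
* The q-value formula (above) is intentionally not a proper BH
  adjustment; consumers needing standard FDR control should apply BH to
  the `p` column.
* The uniform-imputation baseline assumes imputed values do not exceed
  any observed value (required for the implicit-background algebra).
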