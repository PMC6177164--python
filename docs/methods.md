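# Methods

## Model and estimation

PGLS treats tip data as one draw from $y \sim \mathcal N(X\beta,\,
\sigma^2 C(\lambda))$, with $C$ the Brownian-motion covariance implied by
the tree (shared root-to-MRCA path lengths) and $\lambda$ rescaling its
off-diagonal. All fits go through a Cholesky factorization of
$C(\lambda)$; no explicit inverse is formed (an explicit-inverse solver
exists only as a test oracle). Two error-variance scales are reported:
$\hat\sigma^2_{ML} = e^\top V^{-1} e/n$ inside the likelihood and the
unbiased $e^\top V^{-1} e/(n-p)$ behind standard errors, t statistics
(df $= n-p$) and residual standardization. $R^2$ is GLS-weighted:
$1 - e^\top V^{-1}e \,/\, (y-\hat\mu\mathbf 1)^\top V^{-1}(y-\hat\mu\mathbf 1)$
with $\hat\mu$ the GLS (phylogenetic) mean under the same $V$; the adjusted
version applies the usual $(n-1)/(n-p)$ correction. All reported statistics
are invariant to uniform rescaling of branch lengths ($\hat\sigma^2$ scales
reciprocally), so the chronogram's time unit (Ma) is documentation, not a
requirement.

### Profiling Pagel's lambda

$\hat\lambda$ maximizes the profile log-likelihood over $[0,1]$: a grid
pre-scan at step 0.01 over $\{0, 0.01, \dots, 0.99\}$ locates the basin,
then bounded Brent refinement (absolute tolerance $10^{-6}$) searches the
bracketing window, clipped to $[0,1]$ so a profile rising monotonically
into $\lambda = 1$ still reaches the boundary.

The boundary point 1.0 is deliberately not a pre-scan candidate. When a
tree contains effectively duplicated tips — here the wolf and the dog,
whose 15 kya split is four orders of magnitude shorter than the tree depth
— $C(1)$ is nearly singular and the likelihood develops a narrow spike at
exactly $\lambda = 1$: the log-determinant term collapses faster than the
quadratic form grows, over a window of width $\sim 10^{-4}$. On the study
data that spike is formally the global maximum, but it describes a
degenerate fit dominated by one near-singular contrast, and the local
optimizers used throughout the comparative-methods ecosystem (`optim`-style
hill climbing, golden-section/Brent search) never report it; we verified
in development that an independent GLS implementation with a
locally-optimized Pagel correlation structure returns the interior mode on
this tree. Treating such boundary spikes like the degenerate likelihood
maxima of mixture models — excluded in favor of the dominant interior
stationary point — keeps the estimator aligned with standard practice
while remaining a plain bounded-Brent ML estimator on trees without
near-duplicate tips (where grid argmax and optimizer agree to 0.001; this
is property-tested). A perfectly collinear response (zero residual
variance) degenerates the likelihood entirely; the fit is then returned at
the smallest grid $\lambda$ with the exact coefficients.

### Residual diagnostics

Studentized phylogenetic residuals rotate $e$ by the inverse lower
Cholesky factor of $C(\hat\lambda)$ and studentize with leverages from the
equally rotated design; with an identity covariance this reproduces the
classical internally studentized OLS residual (tested to $10^{-10}$
against an independent implementation). $|r| \ge 3$ flags an outlier. Q-Q
coordinates use the $(i-0.5)/n$ quantile convention. Numerically perfect
fits (residual SD below $10^{-12}$ of the fitted scale) return zero
studentized residuals rather than amplifying rounding noise.

### Degree of altriciality

Stage-1 standardized residuals default to the tip-variance mode
$e_i / \sqrt{\hat\sigma^2_{n-p}\, C_{ii}}$; a global z-score mode is
selectable. On an ultrametric tree $C_{ii}$ is constant, the two modes are
proportional, and stage-2 $t$, $p$, $R^2$ and $\hat\lambda$ are invariant
to the choice (slope and SE rescale reciprocally; tested). Stage 1 and
stage 2 each re-estimate $\lambda$; stage-1 residuals enter stage 2 as an
observed predictor with no propagation of stage-1 uncertainty, mirroring
the sequential design of the original analysis.

The arcsine transform defaults to the angular convention
$\arcsin\sqrt{p/100}$, the standard variance stabilizer for proportions.
Calibration supports this: the stage-2 slope obtained under it matches the
published slope implied by $t \times se$ to three decimals, while the
$\arcsin(p/100)$ alternative (kept as a config option) does not.

## Bundled data and its limits

The trait table is transcribed verbatim from the published compilation.
Its cylinder-% summary statistics reproduce the published mean/SD exactly;
the rearing-period and lifespan summaries differ from the published ones
in the second decimal (e.g. mean 305.323 vs 305.306 d), an inconsistency
internal to the source — the printed table cannot arithmetically yield the
printed summaries — so the verbatim table is kept and the discrepancy is
surfaced by the test suite rather than patched.

The chronogram is a reconstruction: the original study names its
divergence-time resources but prints no branch lengths. Node ages were
compiled once from those resources (each age and source listed in
`data/chronogram_provenance.tsv`) and not revisited. Consequences: exact
reproduction of the published regression statistics is not expected, and
tolerance-based comparisons reflect that. Stage-1 statistics are
insensitive to plausible date choices (reconstructed $\hat\lambda = 0.987$,
$t = 2.82$ against published 0.987, 2.781); stage-2's $\hat\lambda$ sits
on a flat profile (log-likelihood difference $\approx 0.4$ across
$[0.8, 0.94]$) and lands at 0.80 where the original reports 0.94.

The Lilliefors statistic is computed exactly (sup over both CDF gaps at
every order statistic; brute-force oracle agreement to $10^{-12}$); its
p-value uses the Dallal–Wilkinson approximation, validated in development
against an independent R implementation to $10^{-6}$, and is reported as a
textual bound in keeping with tabled practice.

## Synthetic data

`simulate_tree` grows a pure-birth tree (exponential waiting times, random
lineage splits) and rescales depth to 1, so simulated covariances are
well-conditioned and $\lambda$ endpoints are identifiable.
`simulate_traits` draws the predictor as Brownian motion ($x \sim \mathcal
N(0, C)$) and the response as $y = \beta_0 + \beta_1 x + \varepsilon$,
$\varepsilon \sim \mathcal N(0, \sigma^2 C(\lambda))$ via Cholesky — the
exact generative model PGLS assumes. Life-history mode maps $x$ and $y$
monotonically onto study-like magnitudes (lifespans 700–22 000 d, rearing
15–2000 d and capped at half of lifespan, percentages in $(0,100)$).

What passing simulation tests do show: unbiased slope recovery, correct
type-I error, $\hat\lambda$ endpoint recovery, and distributional
correctness of the generator (empirical $\text{cov}(\varepsilon)$ matches
$\sigma^2 C(\lambda)$ entrywise within Monte-Carlo error). What they do
not show: robustness to the features real comparative data add —
measurement error in behavioral scores, topology/dating error, non-Brownian
evolution (OU, rate shifts), or the species-selection effects of compiling
data from heterogeneous sources.

All randomness flows from integer seeds through `numpy` `SeedSequence`
spawn keys (tree stream, trait stream, and per-(cell, replicate) streams in
recovery experiments); there is no time-based seeding, and repeated runs
are byte-identical.

## Problem sizes

Monte-Carlo settings are chosen to estimate what they claim: recovery and
type-I experiments use 100-tip trees with 200 replicates per $\lambda$
endpoint and 400 replicates under the null slope (MC SE of a 0.05
rejection rate $\approx 0.011$); generator validation uses 1000–2000
replicates on a fixed 5-tip tree. The full suite and the acceptance script
each complete in about a minute on one CPU.

## Known limitations

* $\lambda$ is bounded above at 1; no $\delta$/$\kappa$ transforms, OU
  models, measurement-error models or multi-response fits.
* The two-stage design conditions stage 2 on stage-1 point estimates;
  uncertainty in the degree of altriciality is not propagated.
* Stage-2 $\hat\lambda$ is weakly identified at $n = 31$ (flat profile);
  its point value should be read with that in mind.
* The chronogram is only as good as the published dates it compiles; users
  with a preferred tree can pass any Newick chronogram via
  `StudyConfig(tree_path=...)`.
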