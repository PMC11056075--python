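# Methods

## The question and the model

Meta-analyses in acute-care fields often combine randomized controlled
trials (RCT) with non-randomized studies (NRS). NRS carry confounding that
can bias a naïvely pooled estimate, so the substantive question is whether
the two designs should share one pooled effect at all. `metapool` frames
this as Bayesian model comparison on the normal-normal hierarchical model
(NNHM):

* data layer: `y_i | θ_i ~ N(θ_i, σ_i²)`, with `y_i` a study's log odds
  ratio or log risk ratio and `σ_i` its (known, plugged-in) standard error;
* effect layer: `θ_i | μ, τ ~ N(μ, τ²)`, with `μ` the pooled log effect and
  `τ` the between-study SD on the log scale;
* priors: `μ ~ N(0, 2²)` — a weakly informative prior spanning odds ratios
  from about 0.02 to 50 at ±2 SD — and `τ ~` half-normal(0.5) or
  half-Cauchy(0.5). At scale 0.5 these place 58% and 43% of their mass
  below τ = 0.4 respectively, i.e. they are weakly informative for the
  small-to-moderate heterogeneity typical of binary mortality-type
  outcomes; the half-Cauchy's heavier tail concedes more to large τ.

All internal computation is on the natural-log scale; OR/RR exponentiation
happens only in reporting. The normality assumption of the effect layer is
the standard one for log effects.

## Marginal likelihood by quadrature

Conditional on τ the model is jointly normal, so

* `μ | τ, y` is normal with precision `Σ 1/(σ_i²+τ²) + 1/s₀²`;
* `p(y | τ)` is a multivariate normal with covariance
  `diag(σ_i²+τ²) + s₀²·J`. Its density is evaluated through the
  matrix-determinant lemma and Sherman–Morrison (rank-one update), so no
  dense solve is ever needed and the cost is O(k) per τ.

The remaining integral `p(y) = ∫ p(y|τ) p(τ) dτ` is computed on the
compactified axis `u = τ/(τ+s)` (s = prior scale), which maps `[0, ∞)` to
`[0, 1)` and places half of the quadrature effort below the prior scale.
The integrand is first evaluated in log space on a 401-point midpoint grid;
its maximum provides an exponent shift, after which adaptive Gauss–Kronrod
quadrature (`scipy.integrate.quad`, relative tolerance 1e-10) integrates
the shifted integrand. A fit whose estimated error on the log marginal
likelihood exceeds 1e-8 is flagged unconverged rather than silently
reported — mirroring the practical reality that some small or degenerate
meta-analyses do not yield computable Bayesian summaries. Likelihood sums
use log-sum-exp throughout; products of up to 60 normal densities would
otherwise underflow.

The same 401-point grid, renormalized, is stored as the discretized
posterior `p(τ|y)`; the marginal posterior of μ is the corresponding
mixture of conditional normals. Mixture components with weight below 1e-13
are dropped (mass error ≲1e-10) to keep quantile searches fast. Posterior
point estimate: the median (mean also stored).

## Credible intervals

Credible intervals are the *shortest* interval containing 95% mass. For a
lower endpoint at quantile level `a`, the width `Q(a+0.95) − Q(a)` is
scanned on a coarse grid over `a ∈ [0, 0.05]` (the width function need not
be unimodal when the posterior is multimodal) and then minimized locally by
bounded scalar search. For unimodal posteriors — the usual case — this is
the highest-posterior-density interval; for multimodal mixtures the
shortest single interval is returned and flagged. Quantiles of the normal
mixture are found by bracketed Brent root-finding on a cached CDF grid
(tolerance 1e-12).

## Model comparison and averaging

Two data models are entertained with prior probability 0.5 each: *pooled*
(all studies share one (μ, τ)) and *separate* (RCT and NRS subgroups get
independent NNHMs with the same priors, so the separate marginal likelihood
is the product of the subgroup marginal likelihoods). The Bayes factor
`BF = p(y|pooled)/p(y|separate)` is thresholded at 3 and 1/3 with strict
inequalities; boundary values are indeterminate. The posterior model
probability is `odds/(odds+1)` with `odds = BF × prior odds`.

The reported posterior is the mixture `pp·(μ | pooled) + (1−pp)·(reported
effect | separate)`. Under the separate model there is no single pooled
effect, so a choice is forced: the default takes the RCT-subgroup posterior
as the separate-model reported effect, on the rationale that the randomized
estimate is the inferential target and NRS are co-data whose influence
should vanish under conflict. This is a genuine design choice, exposed as
`separate_component ∈ {"rct", "nrs", "mixture"}` and recorded in output
metadata rather than silently fixed.

Single-study subgroups are fitted, not refused — the prior then dominates —
because 1-RCT meta-analyses are common in this literature.

## Frequentist estimators

* **DSL**: moment estimator `τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))` with
  fixed-effect weights `w_i = 1/σ_i²`; random-effects weights
  `1/(σ_i²+τ²)`; z-based 95% CI. τ² = 0 for k = 1.
* **HKSJ-DSL**: same point estimate; variance replaced by the weighted
  dispersion `Σw*_i(y_i−μ̂)²/((k−1)Σw*_i)` and `t_{k−1}` quantiles
  (unmodified method, no small-sample truncation). k = 2 fits are computed
  but flagged unstable: the `t₁` quantile (12.71) makes them enormous, and
  they are a plausible reason such fits are sometimes reported as
  incomputable in practice.
* **IVhet**: fixed-effect weights with variance `Σŵ_i²(σ_i²+τ²_DSL)` —
  wider intervals without re-weighting; reduces exactly to the
  inverse-variance fixed-effect analysis when τ²_DSL = 0. The τ² plugged in
  is the DSL moment estimate (configurable in principle, fixed here for
  comparability).

z-based intervals for DSL/IVhet and t-based for HKSJ match the conventional
software implementations these estimators are compared against.
"Statistical significance" everywhere means the interval excludes OR/RR = 1
(0 on the log scale); no Bayesian p-values are computed.

## Effect sizes and I/O

2×2 tables are converted by the standard Woolf formulas; a continuity
correction of 0.5 is added to all four cells (log OR) or both arms' events
and totals (log RR) if and only if a zero cell occurs — never selectively,
matching the RevMan/metan convention. How the original meta-analyses
handled zero cells is not documented; the 0.5 convention is an assumption.
Degenerate tables (no events anywhere, or no non-events) are dropped with a
logged count rather than failing the dataset. CSVs round-trip at full float
precision (shortest-repr writing, round-trip parsing).

## Synthetic cohorts

No real per-study data are distributed with the package, so the generator
emulates the reported cohort structure: per-meta study count from a
discrete log-normal with median 9 clipped to [2, 60]; RCT share from
Beta(2, 4) (median ≈ 0.33, range effectively 0.05–0.8 at these counts),
always ≥ 1 study of each design; latent effects `θ_i ~ N(μ + δ·1[NRS], τ²)`
with defaults μ = log 0.75 (a moderate protective effect typical of the
interventions studied), τ = 0.25 (the cohort's median DSL τ) and δ = 0;
binomial mode draws control risks uniformly on (0.05, 0.40), arm sizes
uniformly on [20, 500], and maps treatment risk through the logit (OR) or
log (RR) link, rejection-resampling draws whose implied risk leaves (0, 1)
or whose table carries no information; normal mode draws
`σ_i = 0.55/√χ²₄` (median ≈ 0.3) for direct (y, se) studies. A master seed
spawns per-dataset child seeds via `SeedSequence([seed, index])`, so any
dataset is individually regenerable.

What the generator does **not** emulate: confounding mechanisms inside NRS
(bias enters only as a mean shift δ), publication/selection effects,
correlated arms, or non-normal random effects. Passing tests on synthetic
cohorts therefore demonstrate the estimators' internal correctness and the
direction of frequentist-vs-Bayesian differences under the stated
generating process — not the magnitude of those differences in any real
literature.

## Verification strategy and problem sizes

Every numerical path is checked against an independent oracle: the
frequentist estimators against formula-by-formula hand evaluation (1e-10)
and against R `metafor` (DL and Knapp–Hartung); the rank-one likelihood
against dense multivariate-normal densities; the quadrature marginal
likelihood against 10⁶-draw Monte-Carlo integration over the priors (3 MC
SE); the shortest interval against dense grid search (1e-3); parameter
recovery on 20 synthetic meta-analyses of 50 studies each (3 MC SE of the
replicate mean). Decision-rule behaviour on real published values is
checked against the packaged transcription of the source cohort's
Bayes-factor table. Simulation-based directional tests use 60–100 seeded
replicates of k = 9–20 meta-analyses — sizes chosen so the full suite runs
in a few minutes while keeping each stochastic assertion at ≥ 3-SE
separation from its threshold.

## Known limitations

* Standard errors are treated as known (the usual NNHM simplification);
  very sparse tables make this questionable.
* The separate-model "reported effect" is a convention (see above); Bayes
  factors themselves are prior-sensitive, and the scale-0.5 priors are a
  fixed choice, not an estimate.
* The shortest-interval search returns a single interval even when the HPD
  region is a union of intervals (flagged, not resolved).
* One printed posterior-model-probability entry in the packaged table is
  internally inconsistent with its own Bayes factor (Wieczorek, half-normal
  prior); integrity checks report it rather than correcting it.
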