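# Methods

This note documents the models, estimation procedures, simulation
design and numerical choices behind the package, including the places
where a design decision was genuinely open and what we chose.

## Models

Four dynamical systems share one interface (`clv.models`):

| kind     | state space          | right-hand side                              |
|----------|----------------------|----------------------------------------------|
| `glv`    | concentrations `x`   | `dx_i/dt = x_i (g_i + Σ_j A_ij x_j + Σ_p B_ip u_p)` |
| `clv`    | alr coordinates `η`  | `dη_i/dt = ḡ_i + Σ_j Ā_ij π_j + Σ_p B̄_ip u_p` |
| `alr`    | alr coordinates `η`  | `dη/dt = ḡ + Ā η + B̄ u` (affine in `η`)      |
| `linear` | compositions `π`     | `dπ/dt = g + A π + B u` (affine in `π`)       |

cLV is the gLV system seen through the additive log-ratio transform
after choosing concentration units with mean community size 1; its
parameters are differences against a denominator taxon
(`ḡ_i = g_i − g_D`, etc., `clv.glv_to_clv`).  The equivalent simplex
form is `dπ_i/dt = π_i (f_i − f̄)` with `f̄ = Σ_k π_k f_k` and the
convention `f_D ≡ 0`, which makes the sum over the D−1 non-denominator
terms equal the composition-weighted mean over all D taxa.  The
`−π_i f̄` term is the compositional correction: it is exactly what is
needed for derivatives to sum to zero on the simplex, and it makes the
simplex vertices fixed points.  The approximation to gLV is controlled
by the community-size signal-to-noise ratio `SNR = 1/Var(N)` (with
`E[N] = 1` after rescaling); `Var(N) > 1` marks the noise-dominated
regime.

Knowing cLV parameters for one denominator determines them for every
other: subtract the new denominator's (implicit-zero-padded) row and
drop it (`clv.change_denominator`).  The map is an involution and leaves
simplex-space forecasts unchanged; both properties are tested to 1e-6.

### Forecasting

Trajectories are integrated with SciPy's adaptive RK45, piecewise over
intervals on which the binary perturbation indicators are constant
(indicators are step functions, right-open, aligned to observation
times).  Each model is integrated in coordinates that respect its
geometry — the source text does not state integration coordinates, so
this was our choice:

* cLV and ALR in alr coordinates (simplex membership is automatic
  through the inverse transform; no projection hacks);
* gLV in log-concentrations, which enforces positivity;
* the linear model in raw compositions; nothing constrains it to the
  simplex, so the raw trajectory is kept and the relative-abundance
  view clips at zero and renormalizes at evaluation time only.

Defaults: `rtol = 1e-6`, `atol = 1e-9`, `max_step` = smallest
inter-observation gap (so short perturbation windows are never stepped
over).  In the gLV log-space right-hand side the exponent is clipped at
250 so a diverging fitted system saturates instead of overflowing
mid-step; the clip only engages at concentrations around 1e108, far
outside any meaningful regime.  Integration failures raise
`ForecastError` carrying the partial trajectory; benchmark folds that
fail are excluded pairwise and recorded.

## Preprocessing

Zeros are handled by pseudocount smoothing of relative abundances,
`π̂_i = (π_i + ε)/(1 + εD)` with `ε = 1e-3` by default, and smoothed
concentrations are rebuilt as `x̂_i = N π̂_i` so relative and absolute
views are treated identically.  Concentrations are rescaled by a single
global scalar — the mean over all observations of the community size —
so that the mean of `N(t)` is exactly 1.  A per-taxon rescaling was
considered and rejected: it would alter relative abundances, whereas a
global factor is a pure change of concentration units.

The alr denominator is chosen as the taxon minimizing the unbiased
sample variance of finite-difference estimates of `d log π_i/dt`,
pooled over within-subject consecutive pairs (differences never cross
subject boundaries); ties break to the lowest taxon index.  For
perturbation interpretation the same selector can be restricted to
observations at/after perturbation onset, and parameters re-expressed
via `change_denominator`.

## Inference: gradient matching

Parameters are estimated without integrating the ODEs: finite-difference
derivative estimates (`Δη/Δt` for cLV/ALR, `Δ log x/Δt` for gLV,
`Δπ/Δt` for linear) are regressed on the model's covariates at the
earlier timepoint of each pair, plus an intercept and the perturbation
indicators.  One-step forward differences only; no smoothing splines or
denoising, so inference quality depends directly on sampling density.

Two penalties are implemented, each with separate weights for the
interaction, growth/intercept and perturbation blocks:

* **ridge** — closed form `(XᵀX + Λ)⁻¹XᵀY`; the intercept is penalized
  with its own weight like any other block (no unpenalized intercept);
* **elastic net** — `α λ_x ‖x‖₁ + α (1 − λ_x) ‖x‖₂²` per block, solved
  by cyclic coordinate descent with fixed sweep order, coefficient
  tolerance 1e-8 and a 10 000-sweep cap (a non-converged fit is
  flagged, not hidden).  The standard elastic-net penalty is used; a
  squared-L1 variant would break coordinate-wise separability and does
  not correspond to the cited estimator.

Predictors are *not* standardized — the models' equations are in raw
covariates — so coefficients are directly interpretable as dynamical
parameters; users comparing against standardizing implementations
should account for this.

**Identifiability on the simplex.**  For models whose covariates are the
full composition (cLV, linear), `Σ_j π_j = 1` makes the intercept column
the exact sum of the state columns: `(g, A)` therefore carry a per-row
additive gauge — adding `c` to `g_i` and subtracting `c` from every
`A_ij` changes nothing.  Only row-centered interactions and
`g_i + mean_j A_ij` are identifiable from data; the penalty resolves the
gauge.  Parameter-recovery tests assert on the gauge-invariant
functionals; comparisons of penalized fits against sampled ground truth
(which is not the minimum-penalty gauge representative) inherit a
constant offset that affects all estimators equally.

Regularization is selected by leave-one-subject-out cross-validation:
for each grid point, fit on all-but-one subject, forecast the held-out
subject from its first observation under its own perturbation schedule,
and accumulate squared error in relative-abundance space (full-trajectory
forecasts, not one-step predictions — chosen because forecast quality is
the quantity benchmarked downstream, and relative-abundance space is the
only space all models share).  The default grid is
`α ∈ {0.1, 0.5, 1, 10}` by `λ ∈ {0.1, 0.5, 0.7, 0.9}` per block; ties
break toward the strongest total penalty, then grid order.

## Evaluation

All trajectory errors are RMSEs in relative-abundance space (absolute
gLV forecasts are normalized first), pooling all residuals per subject;
the initial observation, which every model reproduces exactly, is
excluded.  The benchmark compares each model to cLV per subject with the
paired one-sided Wilcoxon signed-rank test (SciPy's implementation) and
to a constant no-change baseline.  Parameter correspondence fits cLV and
gLV by ridge with identical small penalties (elastic net is avoided here
because it may zero different entries in each model, breaking
entry-by-entry comparison), maps the gLV estimate through the parameter
correspondence, and reports Pearson r per block together with `Var(N)`
and the SNR.  Sign recovery compares cLV parameter signs entry-by-entry
against absolute gLV signs; since `Ā_ij ≈ A_ij − A_Dj`, a disagreement
can only occur where the denominator's column entry dominates
(`|A_ij| < |A_Dj|`), and for interactions drawn symmetrically about zero
the expected agreement is 0.75.

## Synthetic-data generator

The generator emulates a densely sampled gnotobiotic-mouse-style study:
a sparse, stable gLV community observed in several subjects that differ
only in initial conditions.  Defaults (all overridable in
`SimulationConfig`):

| parameter | default | meaning |
|-----------|---------|---------|
| `D` | 10 | taxa |
| `g_mean`, `var_g` | 0.5 /day, 0.05 | positive-truncated normal growth |
| `A_self`, `var_self` | −5.0, 0.25 | negative-truncated normal self-limitation |
| `p_interact` | 0.2 | Bernoulli probability of an off-diagonal interaction |
| `var_interact` | 0.25 | row-degree-scaled: existing `A_ij ~ N(0, var/m_i²)` |
| `x0_mean`, `var_init` | 0.1, 0.0025 | truncated-normal initial concentrations |
| `n_subjects`, `n_timepoints`, `dt_days` | 25, 30, 1 | sampling design |
| `dispersion`, `depth` | 286, 25 000 | Dirichlet–Multinomial sequencing noise |
| `min_mean_abund`, `max_abund` | 0.001, 0.8 | per-subject acceptance filters |

The degree scaling divides interaction variance by the squared row
degree (rows with zero degree have no off-diagonal entries), and the
second argument of every truncated normal is a variance.  The
growth/self-interaction scales were chosen once to give a coexistence
steady state near `x* ≈ g/|A_self| = 0.1` per taxon, hence community
size near 1 and relaxation times of a few days — a stable,
well-observed community.  Hyperparameter values estimated from real
denoised data in the original study were never published, so these are
the package's own defaults.

Interaction matrices are rejection-sampled until *stably dissipative*:
a positive diagonal `W` exists with `WA + AᵀW` negative semidefinite,
certifying a globally stable coexistence equilibrium.  The test tries
`W = I` (negative definiteness of `A + Aᵀ`) first and, for `D ≤ 6`,
searches a 7-point log grid per diagonal entry (first entry pinned to 1;
the criterion is scale-invariant).  For larger `D` only the symmetric
surrogate is used — conservative, and nearly always satisfied under the
defaults because the diagonal dominates.

Per subject, initial conditions are drawn and the system integrated; a
subject is redrawn if any taxon's mean relative abundance falls to
0.001 or below, or any abundance exceeds 0.8 (no taxon effectively
extinct, none taking over).  After all subjects are accepted,
concentrations are rescaled to mean community size 1 and the interaction
matrix is rescaled by the same factor, so the returned parameters
generate the returned data exactly; ground-truth cLV parameters are the
exact map of the gLV truth at the last taxon (any denominator is
equivalent via `change_denominator`).

Sequencing noise draws `q ~ Dirichlet(s·π)` with total concentration
`s = 286` and then `counts ~ Multinomial(depth, q)`; the dispersion
parameter is read as the total Dirichlet concentration (`α_i = s π_i`),
which reproduces the standard Dirichlet–Multinomial moments
`Var(c_i) = depth·π_i(1−π_i)(depth+s)/(1+s)` (verified against this
closed form in the tests).  Exact-zero compositions give exact-zero
counts.  `with_community_size_noise` additionally emulates a fluctuating
total biomass: each observation's composition is scaled by an iid
lognormal community size with mean 1 and a chosen variance — the
controlled setting for studying how the cLV/gLV correspondence degrades
with `Var(N)`.

**What the generator does not emulate:** extinction/colonization (the
log-ratio framework assumes every taxon persists), autocorrelated or
state-dependent biomass fluctuations, taxon-specific sequencing
efficiency, and measurement noise on qPCR totals.  Passing tests
therefore demonstrate correctness of the machinery and reproduction of
the qualitative simulation findings under these idealized conditions,
not performance on real data with those complications.

## Scaled-down study sizes

The replicated experiments in the tests and acceptance script use
deliberately modest problem sizes, chosen as the smallest designs that
express each qualitative effect clearly: 10 replicates of a 10-taxon,
25-subject community for the regularizer and sequencing-depth
comparisons (with the elastic net/ridge contrast evaluated on 5-subject
subsamples, the low-sample regime where sparsity helps most); a 5-taxon,
25-subject community with six noise replicates per variance level for
the correspondence sweep; ~10⁴ Monte-Carlo entries for the
sign-recovery probability.  The fixed operating points for these
comparisons (elastic net `α = 0.1`, `λ = 0.9`; ridge `λ = 0.1`) are
moderate penalties chosen a priori — per-experiment cross-validated
selection would multiply runtime by the grid size without changing the
qualitative contrasts.

## Known limitations

* Gradient matching is consistent only as sampling becomes dense;
  day-scale sampling of day-scale dynamics yields biased derivative
  estimates, so absolute parameter RMSEs are dominated by
  finite-difference error even without sequencing noise (comparisons
  between estimators remain meaningful).
* No statistical model of sequencing noise is used during inference;
  pseudocounts make rare taxa's log-ratios sensitive to small count
  differences.
* The stably-dissipative screen is sufficient, not necessary, for
  `D > 6`; some stable matrices are rejected.
* The cLV/linear gauge (above) means reported `g` and `A` blocks are
  penalty-dependent representatives; only gauge-invariant functionals
  should be interpreted quantitatively.
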