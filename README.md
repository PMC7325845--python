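# clv — compositional Lotka–Volterra modelling of microbiome time series

Sequencing-based surveys of microbial communities measure *relative*
abundances: each sample is a composition living on the simplex, while
classical ecological models such as generalized Lotka–Volterra (gLV)
describe *absolute* concentrations.  Fitting gLV to compositions is a
category error that can invert inferred interactions.  This package
implements **compositional Lotka–Volterra (cLV)**, a nonlinear dynamical
system defined directly on relative abundances, together with the tools
needed to infer, simulate, benchmark and interpret it.  It is aimed at
researchers analysing longitudinal 16S/metagenomic studies (optionally
with qPCR biomass measurements) and at methods developers who need a
reference implementation and simulation framework.

## The model

Let `x_i(t)` be absolute concentrations following gLV,

    dx_i/dt = x_i ( g_i + Σ_j A_ij x_j + Σ_p B_ip u_p(t) ),

with growth rates `g`, interaction matrix `A`, and effects `B` of binary
perturbations `u_p` (antibiotics, diet shifts, ...).  Writing
`π_i = x_i / N` for relative abundances (`N = Σ x_j` the community size)
and taking the additive log-ratio (alr) transform
`η_i = log(π_i / π_D)` with respect to a denominator taxon `D` gives,
after rescaling concentrations so the mean community size is 1,

    dη_i/dt ≈ ḡ_i + Σ_j Ā_ij π_j + Σ_p B̄_ip u_p  =:  f_i(π)

with *relative* parameters `ḡ_i = g_i − g_D`, `Ā_ij = A_ij − A_Dj`,
`B̄_ip = B_ip − B_Dp`.  This is cLV.  Equivalently, on the simplex,

    dπ_i/dt = π_i ( f_i − f̄ ),      f̄ = Σ_k π_k f_k  (with f_D ≡ 0),

a replicator-like form in which `−π_i f̄` acts as the compositional
correction enforcing `Σ π = 1`.  The approximation quality is governed
by a community-size signal-to-noise ratio `SNR = 1 / Var(N)`; when
`Var(N) > 1` after rescaling, relative and absolute parameter estimates
diverge.

The package also implements the natural comparators — gLV itself, a
linear model in alr coordinates (ALR), and a linear model in relative
abundances — so all four can be fit with the *same* gradient-matching
elastic-net/ridge procedure and compared by leave-one-subject-out
forecast error, plus:

* pseudocount smoothing, global concentration rescaling, data-driven
  denominator selection, and exact re-expression of cLV parameters under
  a different denominator;
* a synthetic-data generator (sparse stably-dissipative gLV communities,
  Dirichlet–Multinomial sequencing noise with dispersion 286);
* parameter-correspondence analysis (cLV vs mapped gLV, Pearson r per
  block, Var(N)/SNR) and interaction sign-recovery with network export.

## Worked example

```sh
clv simulate --seed 1 --taxa 5 --subjects 6 --timepoints 20 -o demo
clv choose-denominator --dataset demo/counts.tsv --value-kind counts
clv fit --dataset demo/counts.tsv --value-kind counts --model clv -o demo/fit_clv.json
clv correspond --dataset demo/concentrations.tsv -o demo/corr.json
```

The first command writes Dirichlet–Multinomial counts
(`demo/counts.tsv`), noise-free concentrations and the ground-truth
parameters.  `choose-denominator` prints `taxon_1` — the taxon whose log
relative abundance drifts least over time, hence the safest alr
reference.  The `correspond` run logs

```
INFO clv: Var(N)=0.004678, SNR=213.8, Pearson r: {'interactions': 0.9876, 'growth': 0.9892}
```

read: this simulated community keeps a nearly constant total size
(`Var(N) ≈ 0.005` after mean-1 rescaling, SNR ≈ 214, far from the
noise-dominated `Var(N) > 1` regime), and accordingly the interactions
inferred from relative abundances alone correlate at `r ≈ 0.99` with the
(mapped) interactions inferred from absolute concentrations — exactly
what the cLV/gLV correspondence predicts when community size is stable.

The same things are available as a library:

```python
import clv
cfg = clv.SimulationConfig(D=5, n_subjects=6, n_timepoints=20, seed=1)
dataset, glv_truth, clv_truth = clv.simulate_dataset(cfg)
report = clv.loocv_forecast_benchmark(dataset.to_relative(),
                                      model_kinds=("clv", "linear", "constant"))
```

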