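"""Synthetic longitudinal microbiome data from generalized Lotka-Volterra.

The generator draws sparse, stable gLV communities, integrates them per
subject, and optionally corrupts the compositions with
Dirichlet-Multinomial sequencing noise.  Growth rates are positive
truncated normals, self-interactions negative truncated normals, and
each off-diagonal interaction exists with probability ``p_interact``
(0.2, the sparsity observed in real gut communities); existing
interactions in a row of degree m have variance ``var_interact / m²``.
Interaction matrices are rejection-sampled until they are stably
dissipative, which guarantees a coexistence steady state, and simulated
subjects are redrawn until every taxon keeps a mean relative abundance
above ``min_mean_abund`` and none exceeds ``max_abund``.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import stats

from .dataset import Subject, TimeSeriesSet
from .models import ForecastError, forecast, glv_to_clv
from .params import CLVParams, GLVParams
from .transforms import rescale_concentrations

_REJECT_CAP = 10_000
_SUBJECT_CAP = 1_000


@dataclass(frozen=True)
class SimulationConfig:
    """All hyperparameters of the synthetic-data generator.

    Units: times in days, growth rates per day, interactions per unit
    (rescaled) concentration per day.  ``dispersion`` is the total
    Dirichlet concentration of the sequencing-noise model; ``depth`` the
    number of reads per sample.  Defaults yield a stable, sparsely
    coupled 10-taxon community whose size stays near 1, sampled daily
    over 30 timepoints.
    """

    D: int = 10
    P: int = 0
    g_mean: float = 0.5
    var_g: float = 0.05
    A_self: float = -5.0
    var_self: float = 0.25
    var_interact: float = 0.25
    var_perturb: float = 1.0
    x0_mean: float = 0.1
    var_init: float = 0.0025
    p_interact: float = 0.2
    dispersion: float = 286.0
    depth: int = 25_000
    n_subjects: int = 25
    n_timepoints: int = 30
    dt_days: float = 1.0
    min_mean_abund: float = 0.001
    max_abund: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_interact <= 1.0:
            raise ValueError("p_interact must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.depth < 1:
            raise ValueError("depth must be at least 1")
        for name in ("var_g", "var_self", "var_interact", "var_init", "var_perturb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def _truncated_normal(rng, mean, var, size, sign: str) -> np.ndarray:
    """Normal(mean, var) truncated to the positive or negative half-line."""
    sd = np.sqrt(var)
    if sd == 0:
        return np.full(size, mean)
    if sign == "+":
        a, b = (0.0 - mean) / sd, np.inf
    else:
        a, b = -np.inf, (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def is_stably_dissipative(A: np.ndarray, max_exhaustive: int = 6) -> bool:
    """Test for a positive diagonal W with ``WA + AᵀW`` negative semidefinite.

    Such a W certifies dissipativity, which for Lotka-Volterra systems
    guarantees a globally stable coexistence steady state.  The fast
    sufficient check ``A + Aᵀ`` negative definite (W = I) is tried
    first; for D ≤ ``max_exhaustive`` a log-spaced grid over diagonal
    scalings is searched as well.  The criterion is invariant to
    rescaling W, so the first diagonal entry is pinned to 1.
    """
    A = np.asarray(A, dtype=float)
    D = A.shape[0]
    if A.shape != (D, D):
        raise ValueError("A must be square")
    if np.any(np.diag(A) >= 0):
        return False
    tol = 1e-10
    if np.max(np.linalg.eigvalsh(A + A.T)) < -tol:
        return True
    if D > max_exhaustive:
        return False
    grid = np.logspace(-1.5, 1.5, 7)
    for tail in itertools.product(grid, repeat=D - 1):
        w = np.concatenate([[1.0], tail])
        M = w[:, None] * A + A.T * w[None, :]
        if np.max(np.linalg.eigvalsh(M)) <= tol:
            return True
    return False


def sample_glv_params(config: SimulationConfig, rng: np.random.Generator) -> GLVParams:
    """Draw one stable, sparse gLV parameter set.

    The interaction matrix is redrawn (up to a cap) until it passes the
    stably-dissipative screen.
    """
    g = _truncated_normal(rng, config.g_mean, config.var_g, config.D, "+")
    for _ in range(_REJECT_CAP):
        A = np.zeros((config.D, config.D))
        np.fill_diagonal(
            A, _truncated_normal(rng, config.A_self, config.var_self, config.D, "-")
        )
        z = rng.random((config.D, config.D)) < config.p_interact
        np.fill_diagonal(z, False)
        degree = z.sum(axis=1)
        for i in range(config.D):
            if degree[i]:
                sd = np.sqrt(config.var_interact) / degree[i]
                A[i, z[i]] = rng.normal(0.0, sd, size=degree[i])
        if is_stably_dissipative(A):
            break
    else:
        raise RuntimeError(
            "no stably dissipative interaction matrix found; reduce "
            "var_interact or p_interact"
        )
    B = rng.normal(0.0, np.sqrt(config.var_perturb), size=(config.D, config.P))
    return GLVParams(g=g, A=A, B=B)


def _default_schedule(config: SimulationConfig) -> np.ndarray:
    """Each perturbation switches on for the middle third of the window."""
    T = config.n_timepoints
    u = np.zeros((T, config.P))
    if config.P:
        u[T // 3 : 2 * T // 3, :] = 1.0
    return u


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    params: GLVParams | None = None,
    schedule: np.ndarray | None = None,
) -> tuple[TimeSeriesSet, GLVParams, CLVParams]:
    """Simulate noise-free concentrations for ``n_subjects`` subjects.

    Per subject, initial concentrations are drawn from a positive
    truncated normal and the gLV system is integrated over
    ``n_timepoints`` observations spaced ``dt_days`` apart; subjects
    failing the abundance filters are redrawn.  Concentrations are then
    rescaled by one global scalar so the mean community size is 1, with
    the interaction matrix rescaled accordingly so the returned
    parameters generate the returned data exactly.  Ground-truth cLV
    parameters use the last taxon as denominator (the choice is
    arbitrary and can be changed losslessly afterwards).

    Returns ``(dataset, glv_truth, clv_truth)``; the dataset holds
    concentrations (use :func:`simulate_counts` to add sequencing noise).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if params is None:
        params = sample_glv_params(config, rng)
    times = np.arange(config.n_timepoints) * config.dt_days
    u = _default_schedule(config) if schedule is None else np.asarray(schedule, float)

    subjects = []
    for s in range(config.n_subjects):
        for _ in range(_SUBJECT_CAP):
            x0 = _truncated_normal(
                rng, config.x0_mean, config.var_init, config.D, "+"
            )
            try:
                traj = forecast("glv", params, x0, times, schedule=u)
            except ForecastError:
                continue
            pi = traj.relative
            if np.all(pi.mean(axis=0) > config.min_mean_abund) and np.all(
                pi <= config.max_abund
            ):
                subjects.append(
                    Subject(f"subject_{s}", times.copy(), traj.native, u.copy())
                )
                break
        else:
            raise RuntimeError(
                "could not draw a subject satisfying the abundance filters; "
                "adjust the generator hyperparameters"
            )

    dataset = TimeSeriesSet(
        subjects=subjects,
        taxon_names=[f"taxon_{i}" for i in range(config.D)],
        perturbation_names=[f"perturbation_{p}" for p in range(config.P)],
        value_kind="concentration",
    )
    mu = dataset.totals().mean()
    dataset = rescale_concentrations(dataset)
    # x -> x/mu turns dx/dt = x(g + Ax + Bu) into dx'/dt = x'(g + (muA)x' + Bu)
    params = replace(params, A=params.A * mu)
    clv_truth = glv_to_clv(params, denominator=config.D - 1)
    return dataset, params, clv_truth


def add_sequencing_noise(
    pi, depth: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-Multinomial sequencing counts for one composition.

    Draws sample proportions ``q ~ Dirichlet(dispersion · π)`` and then
    ``counts ~ Multinomial(depth, q)``.  Exact-zero components of π get
    exact-zero counts.
    """
    pi = np.asarray(pi, dtype=float).ravel()
    if depth < 1:
        raise ValueError("depth must be at least 1")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("pi must sum to 1")
    alpha = dispersion * pi
    q = np.zeros_like(pi)
    pos = alpha > 0
    q[pos] = rng.dirichlet(alpha[pos])
    return rng.multinomial(int(depth), q)


def with_community_size_noise(
    dataset: TimeSeriesSet, var_N: float, rng: np.random.Generator
) -> TimeSeriesSet:
    """Concentrations with fluctuating community size of chosen variance.

    Each observation's composition is scaled by an independent lognormal
    community size with mean 1 and variance ``var_N``.  This emulates a
    community whose total biomass fluctuates around a stable level while
    the compositional dynamics are untouched — the regime in which the
    cLV/gLV parameter correspondence degrades as Var(N) grows.
    """
    if var_N < 0:
        raise ValueError("var_N must be nonnegative")
    rel = dataset.to_relative()
    sigma2 = np.log1p(var_N)
    subjects = []
    for s in rel.subjects:
        N = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), s.n_timepoints)
        subjects.append(replace(s, values=s.values * N[:, None]))
    return replace(rel, subjects=subjects, value_kind="concentration")


def simulate_counts(
    dataset: TimeSeriesSet,
    depth: int,
    dispersion: float,
    rng: np.random.Generator,
) -> TimeSeriesSet:
    """Dirichlet-Multinomial count tables for every observation of a dataset."""
    rel = dataset.to_relative()
    subjects = [
        replace(
            s,
            values=np.array(
                [add_sequencing_noise(row, depth, dispersion, rng) for row in s.values]
            ).astype(float),
        )
        for s in rel.subjects
    ]
    return replace(rel, subjects=subjects, value_kind="counts")
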