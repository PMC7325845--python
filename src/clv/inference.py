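"""Gradient-matching parameter estimation.

Instead of repeatedly integrating the ODEs, parameters are fit by
regressing finite-difference derivative estimates on the model's state
covariates at the earlier timepoint of each within-subject consecutive
pair:

==========  ==========================  ==============================
model       response (one row per pair)  predictors (plus intercept, u)
==========  ==========================  ==============================
cLV         Δη / Δt                      π (all D taxa)
ALR         Δη / Δt                      η (D-1 coordinates)
gLV         Δlog x / Δt                  x (all D taxa)
linear      Δπ / Δt                      π (all D taxa)
==========  ==========================  ==============================

Two penalties are provided: ridge (closed form) and elastic net
(cyclic coordinate descent), each with separate weights for the
interaction, growth/intercept, and perturbation blocks.  Regularization
is selected by leave-one-subject-out cross-validation scored on
forecast error in relative-abundance space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dataset import TimeSeriesSet
from .models import MODEL_KINDS, forecast
from .params import ALRParams, CLVParams, GLVParams, LinearParams
from .transforms import alr

#: regularization grids explored by default: mixing weights λ for each
#: block and overall strengths α
LAMBDA_GRID = (0.1, 0.5, 0.7, 0.9)
ALPHA_GRID = (0.1, 0.5, 1.0, 10.0)
DEFAULT_GRID = tuple(
    itertools.product(ALPHA_GRID, LAMBDA_GRID, LAMBDA_GRID, LAMBDA_GRID)
)

_CD_TOL = 1e-8
_CD_MAX_SWEEPS = 10_000


@dataclass
class GradientDesign:
    """Aligned response/predictor matrices for one model and dataset.

    Predictor columns are ordered ``[intercept | state block | u block]``;
    ``g_cols``/``A_cols``/``B_cols`` record the block slices.  No row
    spans two subjects.
    """

    responses: np.ndarray
    predictors: np.ndarray
    dt: np.ndarray
    subject_of_row: np.ndarray
    model_kind: str
    n_taxa: int
    n_perturbations: int
    denominator: int | None = None
    taxon_names: list[str] = field(default_factory=list)
    perturbation_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.responses.shape[0]
        if self.predictors.shape[0] != n or self.dt.size != n or len(
            self.subject_of_row
        ) != n:
            raise ValueError("row counts differ across design fields")
        if np.any(self.dt <= 0):
            raise ValueError("all time steps must be positive")

    @property
    def n_rows(self) -> int:
        return self.responses.shape[0]

    @property
    def state_dim(self) -> int:
        return self.predictors.shape[1] - 1 - self.n_perturbations

    @property
    def g_cols(self) -> slice:
        return slice(0, 1)

    @property
    def A_cols(self) -> slice:
        return slice(1, 1 + self.state_dim)

    @property
    def B_cols(self) -> slice:
        return slice(1 + self.state_dim, self.predictors.shape[1])


@dataclass
class FitResult:
    """A fitted model plus the penalty under which it was obtained."""

    params: GLVParams | CLVParams | ALRParams | LinearParams
    model_kind: str
    regularization: dict
    objective: float
    n_rows: int
    converged: bool = True
    cv_error: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.objective) and self.objective >= 0):
            raise ValueError("objective must be finite and nonnegative")


def build_design(
    dataset: TimeSeriesSet, model_kind: str, denominator: int | None = None
) -> GradientDesign:
    """Assemble the gradient-matching regression problem for one model.

    The dataset must be strictly positive (pseudocount-smoothed) for the
    log-based models; gLV additionally requires concentration data.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if model_kind in ("clv", "alr"):
        if denominator is None:
            raise ValueError(f"{model_kind} requires a denominator taxon")
        if not 0 <= denominator < dataset.n_taxa:
            raise IndexError(f"denominator {denominator} out of range")
    if model_kind == "glv":
        if dataset.value_kind != "concentration":
            raise ValueError("gLV gradient matching requires concentration data")
        data = dataset
    else:
        data = dataset.to_relative()

    responses, predictors, dts, subj = [], [], [], []
    for s_idx, s in enumerate(data.subjects):
        if s.n_timepoints < 2:
            continue
        V = s.values
        if model_kind != "linear" and np.any(V <= 0):
            raise ValueError(
                f"subject {s.subject_id!r}: zeros present; apply pseudocount "
                "smoothing before building a log-based design"
            )
        dt = np.diff(s.times)
        if model_kind in ("clv", "alr"):
            eta = np.array([alr(row, denominator).values for row in V])
            resp = np.diff(eta, axis=0) / dt[:, None]
            state = V[:-1] if model_kind == "clv" else eta[:-1]
        elif model_kind == "glv":
            resp = np.diff(np.log(V), axis=0) / dt[:, None]
            state = V[:-1]
        else:
            resp = np.diff(V, axis=0) / dt[:, None]
            state = V[:-1]
        ones = np.ones((state.shape[0], 1))
        pred = np.hstack([ones, state, s.perturbations[:-1]])
        responses.append(resp)
        predictors.append(pred)
        dts.append(dt)
        subj.extend([s_idx] * resp.shape[0])
    if not responses:
        raise ValueError("no subject contributes a consecutive observation pair")
    return GradientDesign(
        responses=np.vstack(responses),
        predictors=np.vstack(predictors),
        dt=np.concatenate(dts),
        subject_of_row=np.asarray(subj),
        model_kind=model_kind,
        n_taxa=data.n_taxa,
        n_perturbations=data.n_perturbations,
        denominator=denominator if model_kind in ("clv", "alr") else None,
        taxon_names=list(data.taxon_names),
        perturbation_names=list(data.perturbation_names),
    )


def _params_from_coef(design: GradientDesign, coef: np.ndarray):
    """Reshape a (n_predictors, n_responses) coefficient matrix into params."""
    g = coef[design.g_cols].ravel()
    A = coef[design.A_cols].T
    B = coef[design.B_cols].T
    kind = design.model_kind
    if kind == "clv":
        return CLVParams(g, A, B, denominator=design.denominator)
    if kind == "alr":
        return ALRParams(g, A, B, denominator=design.denominator)
    if kind == "glv":
        return GLVParams(g, A, B)
    return LinearParams(g, A, B)


def _penalty_vectors(design: GradientDesign, lambdas) -> np.ndarray:
    lam_A, lam_g, lam_B = lambdas
    w = np.empty(design.predictors.shape[1])
    w[design.g_cols] = lam_g
    w[design.A_cols] = lam_A
    w[design.B_cols] = lam_B
    return w


def fit_ridge(design: GradientDesign, lambdas=(1e-3, 1e-3, 1e-3)) -> FitResult:
    """Penalized least squares with squared-L2 penalties per block.

    Minimizes ``Σ_k ||y_k - X_k β||² + λ_A||A||² + λ_g||g||² + λ_B||B||²``
    via the closed form ``(XᵀX + Λ)⁻¹ Xᵀ Y`` with ``Λ`` the diagonal
    block penalty.  Each response dimension is an independent problem
    sharing the same design.
    """
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam < 0):
        raise ValueError("penalty weights must be nonnegative")
    X, Y = design.predictors, design.responses
    Lam = np.diag(_penalty_vectors(design, lam))
    G = X.T @ X + Lam
    try:
        coef = np.linalg.solve(G, X.T @ Y)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "normal equations are singular; increase the ridge penalties"
        ) from None
    resid = Y - X @ coef
    w = _penalty_vectors(design, lam)
    objective = float(np.sum(resid**2) + np.sum(w[:, None] * coef**2))
    return FitResult(
        params=_params_from_coef(design, coef),
        model_kind=design.model_kind,
        regularization={"method": "ridge", "lam_A": lam[0], "lam_g": lam[1], "lam_B": lam[2]},
        objective=objective,
        n_rows=design.n_rows,
    )


def fit_elastic_net(
    design: GradientDesign,
    alpha: float,
    lambdas=(0.5, 0.5, 0.5),
    tol: float = _CD_TOL,
    max_sweeps: int = _CD_MAX_SWEEPS,
) -> FitResult:
    """Elastic-net penalized least squares by cyclic coordinate descent.

    Minimizes ``Σ_k ||y_k - X_k β||² + Σ_x [α λ_x ||x||₁ + α(1-λ_x)||x||₂²]``
    with ``x`` ranging over the interaction, growth and perturbation
    blocks.  The solver sweeps coordinates in fixed column order until
    the largest coefficient update falls below ``tol``; it is fully
    deterministic given the design.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    lam = np.asarray(lambdas, dtype=float)
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError("mixing weights must lie in [0, 1]")
    X, Y = design.predictors, design.responses
    mix = _penalty_vectors(design, lam)
    l1 = alpha * mix          # weight on |β_j|
    l2 = alpha * (1.0 - mix)  # weight on β_j²
    col_sq = np.einsum("ij,ij->j", X, X)
    n_pred, n_resp = X.shape[1], Y.shape[1]
    coef = np.zeros((n_pred, n_resp))
    R = Y.copy()  # residual Y - X @ coef
    converged = True
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(n_pred):
            b_old = coef[j].copy()
            # rho_j = X_jᵀ (R + X_j b_old): correlation with partial residual
            rho = X[:, j] @ R + col_sq[j] * b_old
            denom = col_sq[j] + l2[j]
            if denom == 0.0:
                b_new = np.zeros(n_resp)
            else:
                b_new = np.sign(rho) * np.maximum(np.abs(rho) - l1[j] / 2.0, 0.0)
                b_new /= denom
            diff = b_new - b_old
            if np.any(diff):
                R -= np.outer(X[:, j], diff)
                coef[j] = b_new
                delta = max(delta, float(np.max(np.abs(diff))))
        if delta < tol:
            break
    else:
        converged = False
    objective = float(
        np.sum(R**2)
        + np.sum(l1[:, None] * np.abs(coef))
        + np.sum(l2[:, None] * coef**2)
    )
    return FitResult(
        params=_params_from_coef(design, coef),
        model_kind=design.model_kind,
        regularization={
            "method": "elastic_net",
            "alpha": float(alpha),
            "lam_A": lam[0],
            "lam_g": lam[1],
            "lam_B": lam[2],
        },
        objective=objective,
        n_rows=design.n_rows,
        converged=converged,
    )


def _forecast_sq_error(fit: FitResult, subject, dataset_kind: str) -> float:
    """Squared forecast error for one held-out subject, in relative space."""
    V = subject.values
    if fit.model_kind == "glv" and dataset_kind == "concentration":
        x0 = V[0]
        truth = V / V.sum(axis=1, keepdims=True)
    else:
        truth = V / V.sum(axis=1, keepdims=True) if dataset_kind != "relative" else V
        x0 = truth[0]
    traj = forecast(
        fit.model_kind, fit.params, x0, subject.times, schedule=subject.perturbations
    )
    return float(np.sum((traj.relative[1:] - truth[1:]) ** 2))


def select_regularization(
    dataset: TimeSeriesSet,
    model_kind: str,
    grid=DEFAULT_GRID,
    denominator: int | None = None,
    method: str = "elastic_net",
) -> FitResult:
    """Choose (α, λ_A, λ_g, λ_B) by leave-one-subject-out cross-validation.

    For each grid point the model is fit on all-but-one subject and the
    held-out subject is forecast from its first observation under its own
    perturbation schedule; squared error is accumulated in
    relative-abundance space.  The fit returned is refit on the full
    dataset at the best grid point.  Ties are broken by the strongest
    total penalty (largest ``α(λ_A+λ_g+λ_B)``), then by grid order.

    With ``method="ridge"`` grid points are ``(λ_A, λ_g, λ_B)`` triples.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty regularization grid")
    if dataset.n_subjects < 2:
        raise ValueError("cross-validation requires at least two subjects")

    def fit_at(data: TimeSeriesSet, point) -> FitResult:
        design = build_design(data, model_kind, denominator=denominator)
        if method == "elastic_net":
            alpha, *lams = point
            return fit_elastic_net(design, alpha, lams)
        return fit_ridge(design, point)

    if len(grid) > 1:
        errors = np.zeros(len(grid))
        for s in dataset.subjects:
            train = dataset.drop_subject(s.subject_id)
            assert all(t.subject_id != s.subject_id for t in train.subjects)
            for gi, point in enumerate(grid):
                fit = fit_at(train, point)
                try:
                    errors[gi] += _forecast_sq_error(fit, s, dataset.value_kind)
                except Exception:
                    errors[gi] += np.inf

        def strength(point) -> float:
            if method == "elastic_net":
                return point[0] * sum(point[1:])
            return float(sum(point))

        order = sorted(
            range(len(grid)), key=lambda i: (errors[i], -strength(grid[i]), i)
        )
        best = order[0]
        if not np.isfinite(errors[best]):
            raise RuntimeError("every grid point failed during inner forecasting")
    else:
        best, errors = 0, np.array([np.nan])

    final = fit_at(dataset, grid[best])
    final.cv_error = float(errors[best])
    return final
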