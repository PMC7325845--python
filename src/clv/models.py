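"""Right-hand sides of the four dynamical systems and trajectory forecasting.

Models
------
gLV
    dx_i/dt = x_i (g_i + Σ_j A_ij x_j + Σ_p B_ip u_p) on absolute
    concentrations.
cLV
    In alr coordinates, dη_i/dt = f_i(π) with
    f_i = ḡ_i + Σ_j Ā_ij π_j + Σ_p B̄_ip u_p — affine in the full
    composition π.  Equivalently, on the simplex,
    dπ_i/dt = π_i (f_i - f̄) with f̄ = Σ_k π_k f_k and the denominator's
    f set to zero; the -π_i f̄ term is the compositional correction that
    keeps Σπ = 1.
ALR
    dη/dt affine in η itself (a linear system in alr coordinates).
linear
    dπ/dt affine in π, with no simplex constraint.

Forecasting integrates each model with adaptive RK45 in coordinates
that respect its geometry: alr for cLV/ALR, log-concentration for gLV,
raw π for the linear model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ALRParams, CLVParams, GLVParams, LinearParams
from .transforms import alr, alr_inverse

MODEL_KINDS = ("glv", "clv", "alr", "linear")

#: default integrator tolerances
RTOL = 1e-6
ATOL = 1e-9

# exp() of log-concentration states is clipped at this exponent so a
# diverging fitted system saturates instead of overflowing mid-step
_EXP_CLIP = 250.0


def _check_u(u, P: int) -> np.ndarray:
    u = np.zeros(P) if u is None else np.asarray(u, dtype=float).ravel()
    if u.size != P:
        raise ValueError(f"expected {P} perturbation indicators, got {u.size}")
    return u


def glv_rhs(x, u, params: GLVParams) -> np.ndarray:
    """Generalized Lotka-Volterra derivative dx/dt on concentrations."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != params.n_taxa:
        raise ValueError(f"expected {params.n_taxa} concentrations, got {x.size}")
    if np.any(x < 0):
        raise ValueError("concentrations must be nonnegative")
    u = _check_u(u, params.n_perturbations)
    return x * (params.g + params.A @ x + params.B @ u)


def clv_alr_rhs(pi, u, params: CLVParams) -> np.ndarray:
    """cLV derivative in alr coordinates: f_i(π) = ḡ_i + Ā π + B̄ u."""
    pi = np.asarray(pi, dtype=float).ravel()
    if pi.size != params.n_taxa:
        raise ValueError(f"expected composition of length {params.n_taxa}")
    u = _check_u(u, params.n_perturbations)
    return params.g_rel + params.A_rel @ pi + params.B_rel @ u


def clv_simplex_rhs(pi, u, params: CLVParams) -> np.ndarray:
    """cLV derivative dπ/dt on the simplex (zeros in π allowed).

    The denominator's relative growth f is identically zero, so
    f̄ = Σ_k π_k f_k over the non-denominator taxa is the composition-
    weighted mean of all D values.  Components sum to zero whenever π
    sums to one; simplex vertices are fixed points.
    """
    pi = np.asarray(pi, dtype=float).ravel()
    D = params.n_taxa
    if pi.size != D:
        raise ValueError(f"expected composition of length {D}")
    f = np.zeros(D)
    f[params.numerator_taxa()] = clv_alr_rhs(pi, u, params)
    f_bar = pi @ f
    return pi * (f - f_bar)


def alr_linear_rhs(eta, u, params: ALRParams) -> np.ndarray:
    """ALR-model derivative dη/dt = ḡ + Ā η + B̄ u (affine in η)."""
    values = eta.values if hasattr(eta, "values") else np.asarray(eta, dtype=float)
    values = values.ravel()
    if values.size != params.n_taxa - 1:
        raise ValueError(f"expected {params.n_taxa - 1} alr coordinates")
    u = _check_u(u, params.n_perturbations)
    return params.g_rel + params.A_rel @ values + params.B_rel @ u


def linear_rhs(pi, u, params: LinearParams) -> np.ndarray:
    """Linear-model derivative dπ/dt = g + A π + B u (affine in π)."""
    pi = np.asarray(pi, dtype=float).ravel()
    if pi.size != params.n_taxa:
        raise ValueError(f"expected composition of length {params.n_taxa}")
    u = _check_u(u, params.n_perturbations)
    return params.g + params.A @ pi + params.B @ u


def glv_to_clv(params: GLVParams, denominator: int) -> CLVParams:
    """Relative (cLV) parameters implied by absolute gLV parameters.

    ḡ_i = g_i - g_D, Ā_ij = A_ij - A_Dj, B̄_ip = B_ip - B_Dp for the
    D-1 taxa i ≠ D.  The correspondence is exact for the alr derivative
    of a gLV trajectory whenever community size N(t) = 1.
    """
    D = params.n_taxa
    if not 0 <= denominator < D:
        raise IndexError(f"denominator {denominator} out of range for D={D}")
    keep = np.arange(D) != denominator
    return CLVParams(
        g_rel=(params.g - params.g[denominator])[keep],
        A_rel=(params.A - params.A[denominator])[keep],
        B_rel=(params.B - params.B[denominator])[keep],
        denominator=denominator,
    )


def community_size_snr(var_N: float) -> tuple[float, bool]:
    """Signal-to-noise ratio for community size on mean-1-rescaled data.

    With E[N] = 1, SNR = 1 / Var(N).  Returns ``(snr, noise_dominated)``
    where the flag is true when Var(N) > 1, the regime in which cLV and
    gLV parameter estimates are expected to diverge.
    """
    if var_N < 0:
        raise ValueError("variance must be nonnegative")
    if var_N == 0:
        return float("inf"), False
    return 1.0 / var_N, var_N > 1.0


class ForecastError(RuntimeError):
    """Numerical integration failed; carries the partial trajectory."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class Trajectory:
    """A forecast: native-space states plus their relative-abundance view.

    ``space`` names the native representation: ``"alr"`` (cLV/ALR),
    ``"concentration"`` (gLV) or ``"relative-raw"`` (linear model; may
    leave the simplex — ``relative`` holds the clipped, renormalized
    view).
    """

    times: np.ndarray
    native: np.ndarray
    space: str
    relative: np.ndarray


def _segment_bounds(u: np.ndarray) -> list[int]:
    """Observation indices where the perturbation vector changes."""
    breaks = [0]
    for k in range(1, u.shape[0]):
        if not np.array_equal(u[k], u[k - 1]):
            breaks.append(k)
    return breaks


def forecast(
    model_kind: str,
    params,
    initial_state,
    times,
    schedule=None,
    rtol: float = RTOL,
    atol: float = ATOL,
    max_step: float | None = None,
) -> Trajectory:
    """Integrate a model forward from an initial state.

    Parameters
    ----------
    model_kind:
        ``"glv"``, ``"clv"``, ``"alr"`` or ``"linear"``.
    initial_state:
        A strictly positive composition (cLV/ALR: required for the alr
        map; linear: any composition) or positive concentrations (gLV),
        observed at ``times[0]``.
    times:
        Strictly increasing observation times in days.
    schedule:
        Binary perturbation indicators of shape ``(len(times), P)``;
        treated as piecewise constant on right-open intervals aligned to
        the observation times.  ``None`` means no perturbations.

    Integration runs segment-by-segment between perturbation switches
    with SciPy's adaptive RK45.  ``max_step`` defaults to the smallest
    inter-observation gap so that no segment is skipped over.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    times = np.asarray(times, dtype=float).ravel()
    if times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    P = params.n_perturbations
    if schedule is None:
        u = np.zeros((times.size, P))
    else:
        u = np.atleast_2d(np.asarray(schedule, dtype=float))
        if u.shape == (P, times.size) and P != times.size:
            u = u.T
        if u.shape != (times.size, P):
            raise ValueError(f"schedule must have shape ({times.size}, {P})")

    x0 = np.asarray(initial_state, dtype=float).ravel()
    den = getattr(params, "denominator", None)
    if model_kind == "clv":
        y0 = alr(x0, den).values
        rhs = lambda t, y, uk: clv_alr_rhs(alr_inverse(y, den), uk, params)
    elif model_kind == "alr":
        y0 = alr(x0, den).values
        rhs = lambda t, y, uk: alr_linear_rhs(y, uk, params)
    elif model_kind == "glv":
        if np.any(x0 <= 0):
            raise ValueError("gLV initial concentrations must be strictly positive")
        y0 = np.log(x0)
        rhs = lambda t, y, uk: (
            params.g
            + params.A @ np.exp(np.minimum(y, _EXP_CLIP))
            + params.B @ uk
        )
    else:  # linear
        y0 = x0.copy()
        rhs = lambda t, y, uk: linear_rhs(y, uk, params)

    if max_step is None:
        max_step = float(np.min(np.diff(times))) if times.size > 1 else np.inf

    states = [y0]
    if times.size > 1:
        breaks = _segment_bounds(u) + [times.size - 1]
        breaks = sorted(set(b for b in breaks if b < times.size))
        if breaks[-1] != times.size - 1:
            breaks.append(times.size - 1)
        y = y0
        for a, b in zip(breaks[:-1], breaks[1:]):
            t_span = (times[a], times[b])
            t_eval = times[a + 1 : b + 1]
            sol = solve_ivp(
                rhs,
                t_span,
                y,
                method="RK45",
                t_eval=t_eval,
                args=(u[a],),
                rtol=rtol,
                atol=atol,
                max_step=max_step,
            )
            sol_y = np.asarray(sol.y, dtype=float)
            sol_y = sol_y.reshape(len(y0), -1) if sol_y.size else sol_y.reshape(len(y0), 0)
            if not sol.success or sol_y.shape[1] != t_eval.size or not np.all(
                np.isfinite(sol_y)
            ):
                good = sol_y.T[np.all(np.isfinite(sol_y.T), axis=1)] if sol_y.size else np.empty((0, len(y0)))
                partial = _assemble(
                    model_kind, params, times[: len(states) + len(good)],
                    np.vstack([np.array(states), good]) if len(good) else np.array(states),
                )
                raise ForecastError(
                    f"{model_kind} integration failed on [{t_span[0]}, {t_span[1]}]: "
                    f"{sol.message}",
                    partial=partial,
                )
            states.extend(sol_y.T)
            y = sol_y[:, -1]
    return _assemble(model_kind, params, times, np.array(states))


def _assemble(model_kind, params, times, Y: np.ndarray) -> Trajectory:
    if model_kind in ("clv", "alr"):
        rel = np.array([alr_inverse(y, params.denominator) for y in Y])
        return Trajectory(times, Y, "alr", rel)
    if model_kind == "glv":
        X = np.exp(Y)
        tot = X.sum(axis=1, keepdims=True)
        return Trajectory(times, X, "concentration", X / tot)
    # linear: keep the raw trajectory; the relative view clips at zero and
    # renormalizes, since nothing constrains the affine system to the simplex
    rel = np.clip(Y, 0.0, None)
    sums = rel.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return Trajectory(times, Y, "relative-raw", rel / sums)
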