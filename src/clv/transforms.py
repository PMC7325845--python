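"""Compositional coordinate transforms and denominator algebra.

The additive log-ratio (alr) transform maps a strictly positive
composition ``π`` to unconstrained coordinates ``η_i = log(π_i / π_D)``
relative to a chosen denominator taxon ``D``.  All cLV machinery lives
in these coordinates; the helpers here also cover pseudocount smoothing
of zeros, global concentration rescaling, data-driven denominator
selection, and the exact algebra for re-expressing cLV parameters with
respect to a different denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import SUM_TOL, TimeSeriesSet
from .params import CLVParams


@dataclass
class AlrCoordinates:
    """alr coordinates: ``values[i] = log(π_i / π_den)`` for non-denominator taxa.

    Entries follow the original taxon order with the denominator omitted.
    """

    values: np.ndarray
    denominator: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("alr coordinates must be finite")
        if not 0 <= self.denominator <= self.values.size:
            raise IndexError(
                f"denominator {self.denominator} out of range for "
                f"D={self.values.size + 1}"
            )


def _check_composition(pi: np.ndarray, strict: bool = True) -> np.ndarray:
    pi = np.asarray(pi, dtype=float).ravel()
    if strict and np.any(pi <= 0):
        raise ValueError(
            "composition has zero or negative components; apply "
            "smooth_pseudocount before log-ratio transforms"
        )
    if np.any(pi < 0):
        raise ValueError("composition has negative components")
    if abs(pi.sum() - 1.0) > SUM_TOL:
        raise ValueError(f"composition must sum to 1 (got {pi.sum():.12g})")
    return pi


def alr(pi, denominator: int) -> AlrCoordinates:
    """Additive log-ratio transform of a strictly positive composition."""
    pi = _check_composition(pi, strict=True)
    D = pi.size
    if not 0 <= denominator < D:
        raise IndexError(f"denominator {denominator} out of range for D={D}")
    keep = np.arange(D) != denominator
    return AlrCoordinates(np.log(pi[keep] / pi[denominator]), denominator)


def alr_inverse(eta, denominator: int | None = None) -> np.ndarray:
    """Map alr coordinates back to the simplex.

    Overflow-safe: the implied log-composition (with a zero in the
    denominator slot) is max-shifted before exponentiation, so very large
    coordinates saturate instead of overflowing.
    """
    if isinstance(eta, AlrCoordinates):
        denominator = eta.denominator
        values = eta.values
    else:
        if denominator is None:
            raise ValueError("denominator required when eta is a plain array")
        values = np.asarray(eta, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("alr coordinates must be finite")
    D = values.size + 1
    log_pi = np.zeros(D)
    keep = np.arange(D) != denominator
    log_pi[keep] = values
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


def smooth_pseudocount(pi, epsilon: float) -> np.ndarray:
    """Additive smoothing ``π̂_i = (π_i + ε) / (1 + εD)`` of a composition.

    Strictly positive output whose minimum component is at least
    ``ε / (1 + εD)``; the sum-to-one constraint is preserved.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    pi = _check_composition(pi, strict=False)
    smoothed = (pi + epsilon) / (1.0 + epsilon * pi.size)
    return smoothed / smoothed.sum()


def smoothed_concentration(n_total: float, pi_hat) -> np.ndarray:
    """Concentrations implied by a smoothed composition: ``x̂_i = N · π̂_i``."""
    if not n_total > 0:
        raise ValueError("total concentration must be positive")
    pi_hat = _check_composition(pi_hat, strict=False)
    return float(n_total) * pi_hat


def rescale_concentrations(dataset: TimeSeriesSet) -> TimeSeriesSet:
    """Divide all concentrations by one global scalar so mean N(t) is 1.

    The scalar is the mean over every observation (pooled across
    subjects) of the community size ``N(t) = Σ_i x_i(t)``; this is a pure
    change of concentration units and leaves relative abundances
    untouched.
    """
    if dataset.value_kind != "concentration":
        raise ValueError("rescale_concentrations requires concentration data")
    mu = dataset.totals().mean()
    if not mu > 0:
        raise ValueError("mean community size is zero; cannot rescale")
    return dataset.map_values(lambda v: v / mu)


def log_derivative_rows(dataset: TimeSeriesSet) -> np.ndarray:
    """Finite-difference estimates of d/dt log π, one row per consecutive pair.

    Differences never cross subject boundaries.  Returns an array of
    shape (Σ_s (T_s - 1), D).
    """
    rel = dataset.to_relative()
    rows = []
    for s in rel.subjects:
        if np.any(s.values <= 0):
            raise ValueError(
                f"subject {s.subject_id!r}: zero relative abundance; smooth first"
            )
        logs = np.log(s.values)
        dt = np.diff(s.times)[:, None]
        if len(dt):
            rows.append(np.diff(logs, axis=0) / dt)
    if not rows:
        raise ValueError("need at least one within-subject consecutive pair")
    return np.vstack(rows)


def select_denominator(dataset: TimeSeriesSet) -> int:
    """Pick the alr denominator: the taxon whose log relative abundance is
    most nearly constant in time.

    Computes finite-difference estimates of d/dt log π_i over all
    within-subject consecutive pairs and returns the taxon with the
    smallest sample variance (ties broken by lowest index).
    """
    diffs = log_derivative_rows(dataset)
    if diffs.shape[0] < 2:
        raise ValueError("need at least two difference rows to estimate variances")
    variances = diffs.var(axis=0, ddof=1)
    return int(np.argmin(variances))


def change_denominator(params: CLVParams, new_denominator: int) -> CLVParams:
    """Re-express cLV parameters with respect to a different denominator taxon.

    With the convention that the current denominator's (implicit) row is
    zero, the new rows are obtained by subtracting row ``m`` (the new
    denominator) from every row and dropping row ``m``:
    ``ḡ'_i = ḡ_i - ḡ_m``, ``Ā'_ij = Ā_ij - Ā_mj``, ``B̄'_ip = B̄_ip - B̄_mp``.
    The map is an involution: changing back recovers the original
    parameters exactly.
    """
    D = params.n_taxa
    if not 0 <= new_denominator < D:
        raise IndexError(f"denominator {new_denominator} out of range for D={D}")
    if new_denominator == params.denominator:
        return params

    def expand(block: np.ndarray) -> np.ndarray:
        full = np.zeros((D,) + block.shape[1:])
        full[params.numerator_taxa()] = block
        return full

    g_full = expand(params.g_rel[:, None])[:, 0]
    A_full = expand(params.A_rel)
    B_full = expand(params.B_rel)
    keep = np.arange(D) != new_denominator
    return replace(
        params,
        g_rel=(g_full - g_full[new_denominator])[keep],
        A_rel=(A_full - A_full[new_denominator])[keep],
        B_rel=(B_full - B_full[new_denominator])[keep],
        denominator=new_denominator,
    )
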