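"""Parameter containers for the four dynamical models.

Conventions
-----------
Taxa are indexed 0..D-1 in input order and are never reordered.  Models
defined in additive log-ratio coordinates (cLV, ALR) carry an explicit
``denominator`` taxon index; their row dimension is D-1 and rows follow
the original taxon order with the denominator row omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_2d(x, name: str) -> np.ndarray:
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


@dataclass
class GLVParams:
    """Generalized Lotka-Volterra parameters on absolute concentrations.

    ``g`` (per day) are intrinsic growth rates, ``A`` (per unit
    concentration per day) pairwise interactions, ``B`` (per day)
    additive effects of binary external perturbations.
    """

    g: np.ndarray
    A: np.ndarray
    B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = _as_1d(self.g, "g")
        self.A = _as_2d(self.A, "A")
        D = self.g.size
        if self.A.shape != (D, D):
            raise ValueError(f"A must be ({D}, {D}), got {self.A.shape}")
        self.B = np.zeros((D, 0)) if self.B is None else _as_2d(self.B, "B")
        if self.B.shape[0] != D:
            raise ValueError(f"B must have {D} rows, got {self.B.shape}")

    @property
    def n_taxa(self) -> int:
        return self.g.size

    @property
    def n_perturbations(self) -> int:
        return self.B.shape[1]


@dataclass
class CLVParams:
    """Compositional Lotka-Volterra parameters, relative to a denominator taxon.

    Rows cover the D-1 non-denominator taxa (original order); the
    interaction matrix keeps all D columns, including the denominator,
    because the cLV right-hand side is affine in the full composition.
    """

    g_rel: np.ndarray
    A_rel: np.ndarray
    B_rel: np.ndarray | None = None
    denominator: int = 0

    def __post_init__(self) -> None:
        self.g_rel = _as_1d(self.g_rel, "g_rel")
        self.A_rel = _as_2d(self.A_rel, "A_rel")
        Dm1 = self.g_rel.size
        D = Dm1 + 1
        if self.A_rel.shape != (Dm1, D):
            raise ValueError(f"A_rel must be ({Dm1}, {D}), got {self.A_rel.shape}")
        self.B_rel = (
            np.zeros((Dm1, 0)) if self.B_rel is None else _as_2d(self.B_rel, "B_rel")
        )
        if self.B_rel.shape[0] != Dm1:
            raise ValueError(f"B_rel must have {Dm1} rows, got {self.B_rel.shape}")
        if not 0 <= self.denominator < D:
            raise IndexError(f"denominator {self.denominator} out of range for D={D}")

    @property
    def n_taxa(self) -> int:
        return self.A_rel.shape[1]

    @property
    def n_perturbations(self) -> int:
        return self.B_rel.shape[1]

    def numerator_taxa(self) -> np.ndarray:
        """Taxon indices of the D-1 parameter rows, in original order."""
        D = self.n_taxa
        return np.array([i for i in range(D) if i != self.denominator])


@dataclass
class ALRParams:
    """Linear model in alr coordinates: dη/dt is affine in η itself."""

    g_rel: np.ndarray
    A_rel: np.ndarray
    B_rel: np.ndarray | None = None
    denominator: int = 0

    def __post_init__(self) -> None:
        self.g_rel = _as_1d(self.g_rel, "g_rel")
        self.A_rel = _as_2d(self.A_rel, "A_rel")
        Dm1 = self.g_rel.size
        if self.A_rel.shape != (Dm1, Dm1):
            raise ValueError(f"A_rel must be ({Dm1}, {Dm1}), got {self.A_rel.shape}")
        self.B_rel = (
            np.zeros((Dm1, 0)) if self.B_rel is None else _as_2d(self.B_rel, "B_rel")
        )
        if self.B_rel.shape[0] != Dm1:
            raise ValueError(f"B_rel must have {Dm1} rows, got {self.B_rel.shape}")
        if not 0 <= self.denominator <= Dm1:
            raise IndexError(f"denominator {self.denominator} out of range")

    @property
    def n_taxa(self) -> int:
        return self.g_rel.size + 1

    @property
    def n_perturbations(self) -> int:
        return self.B_rel.shape[1]


@dataclass
class LinearParams:
    """Linear model directly in relative abundances (no simplex constraint)."""

    g: np.ndarray
    A: np.ndarray
    B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = _as_1d(self.g, "g")
        self.A = _as_2d(self.A, "A")
        D = self.g.size
        if self.A.shape != (D, D):
            raise ValueError(f"A must be ({D}, {D}), got {self.A.shape}")
        self.B = np.zeros((D, 0)) if self.B is None else _as_2d(self.B, "B")
        if self.B.shape[0] != D:
            raise ValueError(f"B must have {D} rows, got {self.B.shape}")

    @property
    def n_taxa(self) -> int:
        return self.g.size

    @property
    def n_perturbations(self) -> int:
        return self.B.shape[1]
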