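"""In-memory container for multi-subject longitudinal microbiome data.

A :class:`TimeSeriesSet` holds one array block per subject: observation
times (days), a taxa table (counts, relative abundances, or absolute
concentrations; rows are timepoints, columns are taxa) and a binary
perturbation-indicator table aligned to the same timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

VALUE_KINDS = ("counts", "relative", "concentration")

#: absolute tolerance for the sum-to-one check on relative abundances
SUM_TOL = 1e-8


@dataclass
class Subject:
    """Observations for one subject (mouse, patient, replicate...).

    Parameters
    ----------
    subject_id:
        Label used in files and reports.
    times:
        Strictly increasing observation times in days, shape ``(T,)``.
    values:
        Taxa table, shape ``(T, D)``; meaning given by the parent set's
        ``value_kind``.
    perturbations:
        Binary indicators, shape ``(T, P)``. ``u[k, p] = 1`` means
        perturbation ``p`` is active on the right-open interval starting
        at ``times[k]``.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    perturbations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.perturbations = np.asarray(self.perturbations, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"subject {self.subject_id!r}: times must be strictly increasing"
            )
        if self.values.shape[0] != self.times.size:
            raise ValueError(
                f"subject {self.subject_id!r}: values rows != number of times"
            )
        if self.perturbations.ndim != 2 or self.perturbations.shape[0] != self.times.size:
            raise ValueError(
                f"subject {self.subject_id!r}: perturbations must be (T, P)"
            )
        if not np.isin(self.perturbations, (0.0, 1.0)).all():
            raise ValueError(
                f"subject {self.subject_id!r}: perturbation indicators must be 0/1"
            )

    @property
    def n_timepoints(self) -> int:
        return self.times.size


@dataclass
class TimeSeriesSet:
    """Multi-subject longitudinal dataset.

    ``value_kind`` is one of ``"counts"`` (nonnegative integers),
    ``"relative"`` (rows sum to one) or ``"concentration"`` (absolute
    abundances; row sums are the community size ``N(t)``).
    """

    subjects: list[Subject]
    taxon_names: list[str]
    perturbation_names: list[str] = field(default_factory=list)
    value_kind: str = "relative"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if not self.subjects:
            raise ValueError("dataset must contain at least one subject")
        D, P = len(self.taxon_names), len(self.perturbation_names)
        for s in self.subjects:
            if s.values.shape[1] != D:
                raise ValueError(f"subject {s.subject_id!r}: expected {D} taxa")
            if s.perturbations.shape[1] != P:
                raise ValueError(
                    f"subject {s.subject_id!r}: expected {P} perturbations"
                )
            if np.any(s.values < 0):
                raise ValueError(f"subject {s.subject_id!r}: negative values")
            if self.value_kind == "counts" and np.any(s.values != np.round(s.values)):
                raise ValueError(f"subject {s.subject_id!r}: counts must be integers")
            if self.value_kind == "relative":
                sums = s.values.sum(axis=1)
                if np.any(np.abs(sums - 1.0) > SUM_TOL):
                    raise ValueError(
                        f"subject {s.subject_id!r}: relative abundances must sum "
                        f"to 1 (max deviation {np.max(np.abs(sums - 1.0)):.3g})"
                    )

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_perturbations(self) -> int:
        return len(self.perturbation_names)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(f"no subject {subject_id!r}")

    def subset(self, subject_ids: Iterable[str]) -> "TimeSeriesSet":
        """A new set restricted to ``subject_ids`` (order as given)."""
        ids = list(subject_ids)
        return replace(self, subjects=[self.subject(i) for i in ids])

    def drop_subject(self, subject_id: str) -> "TimeSeriesSet":
        kept = [s for s in self.subjects if s.subject_id != subject_id]
        if len(kept) == len(self.subjects):
            raise KeyError(f"no subject {subject_id!r}")
        return replace(self, subjects=kept)

    # -- representations -------------------------------------------------------
    def totals(self) -> np.ndarray:
        """Community size N(t) for every observation, concatenated over subjects."""
        return np.concatenate([s.values.sum(axis=1) for s in self.subjects])

    def to_relative(self) -> "TimeSeriesSet":
        """Convert counts or concentrations to relative abundances."""
        if self.value_kind == "relative":
            return self
        subs = []
        for s in self.subjects:
            tot = s.values.sum(axis=1, keepdims=True)
            if np.any(tot <= 0):
                raise ValueError(
                    f"subject {s.subject_id!r}: zero total at some timepoint"
                )
            subs.append(replace(s, values=s.values / tot))
        return replace(self, subjects=subs, value_kind="relative")

    def smoothed(self, epsilon: float = 1e-3) -> "TimeSeriesSet":
        """Pseudocount-smooth relative abundances (counts are converted first).

        Concentration data keep their per-sample totals: the smoothed
        concentration is the total times the smoothed composition, so both
        relative and absolute views receive the same treatment of zeros.
        """
        from .transforms import smooth_pseudocount, smoothed_concentration

        if self.value_kind == "concentration":
            subs = []
            for s in self.subjects:
                tot = s.values.sum(axis=1)
                rows = [
                    smoothed_concentration(
                        tot[k], smooth_pseudocount(s.values[k] / tot[k], epsilon)
                    )
                    for k in range(s.n_timepoints)
                ]
                subs.append(replace(s, values=np.array(rows)))
            return replace(self, subjects=subs)
        rel = self.to_relative()
        subs = [
            replace(
                s,
                values=np.array(
                    [smooth_pseudocount(row, epsilon) for row in s.values]
                ),
            )
            for s in rel.subjects
        ]
        return replace(rel, subjects=subs)

    def map_values(self, fn) -> "TimeSeriesSet":
        """Apply ``fn`` to every subject's value table (shape preserved)."""
        return replace(
            self, subjects=[replace(s, values=fn(s.values)) for s in self.subjects]
        )

    def zero_fraction(self) -> float:
        """Fraction of exactly-zero entries across all value tables."""
        total = sum(s.values.size for s in self.subjects)
        zeros = sum(int(np.sum(s.values == 0)) for s in self.subjects)
        return zeros / total


def taxon_index(names: Sequence[str], name_or_index) -> int:
    """Resolve a taxon given by name or integer position to its index."""
    if isinstance(name_or_index, (int, np.integer)):
        idx = int(name_or_index)
        if not 0 <= idx < len(names):
            raise IndexError(f"taxon index {idx} out of range for {len(names)} taxa")
        return idx
    try:
        return list(names).index(name_or_index)
    except ValueError:
        raise KeyError(f"no taxon named {name_or_index!r}") from None
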