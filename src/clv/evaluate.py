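"""Evaluation: forecast benchmarking, parameter correspondence, sign recovery.

All trajectory errors are computed in relative-abundance space so that
models defined on different spaces (absolute concentrations, alr
coordinates, raw compositions) are compared on equal footing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import TimeSeriesSet
from .inference import FitResult, build_design, fit_ridge, select_regularization
from .models import ForecastError, Trajectory, community_size_snr, forecast, glv_to_clv
from .params import CLVParams, GLVParams
from .transforms import change_denominator, rescale_concentrations, select_denominator

log = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Bundle of evaluation outputs; unused fields stay ``None``/empty.

    ``per_subject_rmse`` maps model kind -> subject id -> trajectory
    RMSE.  ``squared_error_vs_reference`` holds per-timepoint squared
    error differences of each model relative to cLV (positive values
    mean cLV predicted better at that timepoint).  Wilcoxon p-values
    are one-sided, paired over subjects.
    """

    per_subject_rmse: dict = field(default_factory=dict)
    final_timepoint_rmse: dict = field(default_factory=dict)
    squared_error_vs_reference: dict = field(default_factory=dict)
    wilcoxon_p: dict = field(default_factory=dict)
    pearson_r: dict = field(default_factory=dict)
    parameter_rmse: dict = field(default_factory=dict)
    var_N: float | None = None
    snr: float | None = None
    noise_dominated: bool | None = None
    sign_agreement: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    failed_folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_subject_rmse": self.per_subject_rmse,
            "final_timepoint_rmse": self.final_timepoint_rmse,
            "squared_error_vs_reference": {
                k: {s: list(map(float, v)) for s, v in d.items()}
                for k, d in self.squared_error_vs_reference.items()
            },
            "wilcoxon_p": self.wilcoxon_p,
            "pearson_r": self.pearson_r,
            "parameter_rmse": self.parameter_rmse,
            "var_N": self.var_N,
            "snr": self.snr,
            "noise_dominated": self.noise_dominated,
            "sign_agreement": self.sign_agreement,
            "edges": self.edges,
            "failed_folds": self.failed_folds,
        }


def rmse(a, b) -> float:
    """Root-mean-square error pooled over all entries."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def constant_baseline(initial, times) -> Trajectory:
    """The no-change forecast: repeat the initial composition forever."""
    initial = np.asarray(initial, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    rel = np.tile(initial, (times.size, 1))
    return Trajectory(times, rel.copy(), "relative-raw", rel)


# model kinds accepted by the benchmark, beyond the four dynamical models:
# "glv-abs" fits gLV on concentrations, "glv-rel" treats relative
# abundances as concentrations (constant community size assumption)
BENCHMARK_MODELS = ("clv", "glv-abs", "glv-rel", "alr", "linear", "constant")


def _fit_for_benchmark(train, kind, grid, denominator):
    if kind == "glv-abs":
        return select_regularization(train["conc"], "glv", grid)
    if kind == "glv-rel":
        return select_regularization(train["rel_as_conc"], "glv", grid)
    return select_regularization(
        train["rel"], kind, grid, denominator=denominator
    )


def _forecast_for_benchmark(fit: FitResult, subject_rel, subject_conc):
    if fit.model_kind == "glv" and subject_conc is not None:
        s = subject_conc
        return forecast("glv", fit.params, s.values[0], s.times, s.perturbations)
    s = subject_rel
    return forecast(fit.model_kind, fit.params, s.values[0], s.times, s.perturbations)


def loocv_forecast_benchmark(
    dataset: TimeSeriesSet,
    model_kinds=("clv", "alr", "linear", "constant"),
    grid=((1.0, 0.5, 0.5, 0.5),),
    epsilon: float = 1e-3,
    denominator: int | str = "auto",
    reference: str = "clv",
) -> EvaluationReport:
    """Leave-one-subject-out forecast benchmark across models.

    For each held-out subject, every model selects its regularization by
    an inner leave-one-out on the remaining subjects, is refit, and
    forecasts the held-out subject from its first observation under its
    recorded perturbation schedule.  Reported per subject: trajectory
    RMSE (relative-abundance space, initial point excluded),
    final-timepoint RMSE, and per-timepoint squared-error differences
    against the reference model.  Model pairs are compared with the
    paired one-sided Wilcoxon signed-rank test (H1: reference model has
    lower RMSE).

    ``"glv-abs"`` requires concentration data; a fold whose fit or
    forecast fails is recorded in ``failed_folds`` and dropped from the
    paired comparisons.
    """
    unknown = set(model_kinds) - set(BENCHMARK_MODELS)
    if unknown:
        raise ValueError(f"unknown benchmark models: {sorted(unknown)}")
    if dataset.n_subjects < 2:
        raise ValueError("benchmark requires at least two subjects")
    if "glv-abs" in model_kinds and dataset.value_kind != "concentration":
        raise ValueError("glv-abs requires concentration data")

    rel = dataset.smoothed(epsilon).to_relative()
    conc = (
        rescale_concentrations(dataset.smoothed(epsilon))
        if dataset.value_kind == "concentration"
        else None
    )
    from dataclasses import replace as _replace

    rel_as_conc = _replace(rel, value_kind="concentration")

    report = EvaluationReport()
    for kind in model_kinds:
        report.per_subject_rmse[kind] = {}
        report.final_timepoint_rmse[kind] = {}
        if kind != reference:
            report.squared_error_vs_reference[kind] = {}

    for held in [s.subject_id for s in dataset.subjects]:
        train = {
            "rel": rel.drop_subject(held),
            "rel_as_conc": rel_as_conc.drop_subject(held),
            "conc": conc.drop_subject(held) if conc is not None else None,
        }
        den = (
            select_denominator(train["rel"])
            if denominator == "auto"
            else int(denominator)
        )
        held_rel = rel.subject(held)
        held_conc = conc.subject(held) if conc is not None else None
        truth = held_rel.values
        sq_err = {}
        for kind in model_kinds:
            try:
                if kind == "constant":
                    traj = constant_baseline(truth[0], held_rel.times)
                else:
                    fit = _fit_for_benchmark(train, kind, grid, den)
                    traj = _forecast_for_benchmark(fit, held_rel, held_conc)
            except (ForecastError, RuntimeError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"fold {held!r}, model {kind!r} failed: {exc}")
                report.failed_folds.append({"subject": held, "model": kind})
                continue
            err = traj.relative - truth
            sq_err[kind] = (err**2).sum(axis=1)
            report.per_subject_rmse[kind][held] = rmse(
                traj.relative[1:], truth[1:]
            )
            report.final_timepoint_rmse[kind][held] = rmse(
                traj.relative[-1], truth[-1]
            )
        if reference in sq_err:
            for kind in model_kinds:
                if kind != reference and kind in sq_err:
                    report.squared_error_vs_reference[kind][held] = (
                        sq_err[kind] - sq_err[reference]
                    )

    ref_rmse = report.per_subject_rmse.get(reference, {})
    for kind in model_kinds:
        if kind == reference:
            continue
        shared = sorted(set(ref_rmse) & set(report.per_subject_rmse[kind]))
        if len(shared) < 2:
            continue
        x = [ref_rmse[s] for s in shared]
        y = [report.per_subject_rmse[kind][s] for s in shared]
        if np.allclose(x, y):
            p = 1.0
        else:
            p = float(stats.wilcoxon(x, y, alternative="less").pvalue)
        report.wilcoxon_p[f"{reference}<{kind}"] = p
    return report


def parameter_correspondence(
    dataset: TimeSeriesSet,
    lambdas=(1e-3, 1e-3, 1e-3),
    epsilon: float = 1e-3,
    denominator: int | str = "auto",
) -> EvaluationReport:
    """Compare ridge-fit cLV parameters with mapped ridge-fit gLV parameters.

    The dataset (concentrations required) is pseudocount-smoothed and
    rescaled to mean community size 1.  gLV is fit on concentrations and
    cLV on the corresponding compositions with identical ridge
    penalties; the gLV estimate is mapped through the gLV->cLV
    parameter correspondence at cLV's denominator.  Reported: Pearson r
    per parameter block, Var(N) across all observations after rescaling,
    and the community-size SNR.  Ridge (not elastic net) keeps the two
    estimates directly comparable entry by entry.
    """
    if dataset.value_kind != "concentration":
        raise ValueError("parameter correspondence requires concentration data")
    conc = rescale_concentrations(dataset.smoothed(epsilon))
    rel = conc.to_relative()
    den = select_denominator(rel) if denominator == "auto" else int(denominator)

    clv_fit = fit_ridge(build_design(rel, "clv", denominator=den), lambdas)
    glv_fit = fit_ridge(build_design(conc, "glv"), lambdas)
    mapped = glv_to_clv(glv_fit.params, denominator=den)

    report = EvaluationReport()
    totals = conc.totals()
    report.var_N = float(totals.var(ddof=1))
    report.snr, report.noise_dominated = community_size_snr(report.var_N)

    p: CLVParams = clv_fit.params
    blocks = {
        "interactions": (p.A_rel.ravel(), mapped.A_rel.ravel()),
        "growth": (p.g_rel.ravel(), mapped.g_rel.ravel()),
    }
    if p.n_perturbations:
        blocks["perturbations"] = (p.B_rel.ravel(), mapped.B_rel.ravel())
    for name, (a, b) in blocks.items():
        if a.size < 2:
            continue
        report.pearson_r[name] = float(stats.pearsonr(a, b).statistic)
        report.parameter_rmse[name] = rmse(a, b)
    return report


def sign_recovery(
    clv_fit: CLVParams,
    reference: GLVParams,
    interaction_denominator: int | None = None,
    perturbation_denominator: int | None = None,
    taxon_names=None,
    perturbation_names=None,
) -> EvaluationReport:
    """How often cLV parameter signs match the absolute gLV signs.

    The cLV interaction block is (optionally) re-expressed with respect
    to ``interaction_denominator`` and compared entry-by-entry against
    the gLV interaction signs (rows restricted to non-denominator taxa);
    the perturbation block likewise, possibly under a different
    denominator.  Since Ā_ij ≈ A_ij - A_Dj, the signs agree whenever the
    denominator's effect is small relative to |A_ij|.  Also exports a
    signed, weighted edge list of the cLV network.
    """
    report = EvaluationReport()
    D = clv_fit.n_taxa
    taxon_names = taxon_names or [f"taxon_{i}" for i in range(D)]
    perturbation_names = perturbation_names or [
        f"perturbation_{p}" for p in range(clv_fit.n_perturbations)
    ]

    def agreement(block_rel, block_abs, rows) -> float:
        pred = np.sign(block_rel)
        true = np.sign(block_abs[rows])
        return float(np.mean(pred == true))

    p_int = (
        change_denominator(clv_fit, interaction_denominator)
        if interaction_denominator is not None
        else clv_fit
    )
    rows = p_int.numerator_taxa()
    report.sign_agreement["interactions"] = agreement(p_int.A_rel, reference.A, rows)
    for r, i in enumerate(rows):
        for j in range(D):
            w = p_int.A_rel[r, j]
            report.edges.append(
                {
                    "source": taxon_names[j],
                    "target": taxon_names[i],
                    "sign": int(np.sign(w)),
                    "weight": float(abs(w)),
                    "type": "interaction",
                }
            )

    if clv_fit.n_perturbations:
        p_per = (
            change_denominator(clv_fit, perturbation_denominator)
            if perturbation_denominator is not None
            else clv_fit
        )
        rows = p_per.numerator_taxa()
        report.sign_agreement["perturbations"] = agreement(
            p_per.B_rel, reference.B, rows
        )
        for r, i in enumerate(rows):
            for q in range(clv_fit.n_perturbations):
                w = p_per.B_rel[r, q]
                report.edges.append(
                    {
                        "source": perturbation_names[q],
                        "target": taxon_names[i],
                        "sign": int(np.sign(w)),
                        "weight": float(abs(w)),
                        "type": "perturbation",
                    }
                )
    return report


def write_edge_list(report: EvaluationReport, path) -> None:
    """Write the network edge list as a 5-column TSV."""
    import pandas as pd

    pd.DataFrame(report.edges, columns=["source", "target", "sign", "weight", "type"])[
        ["source", "target", "sign", "weight", "type"]
    ].to_csv(path, sep="\t", index=False)
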