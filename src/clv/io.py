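"""Readers and writers for abundance tables, schedules, and parameter files.

Delimited text only.  The canonical table layout is long format with
columns ``subject, time, taxon, value``; wide format (one column per
taxon) is accepted for convenience.  Perturbation schedules come either
as long-format indicator tables (``subject, time, perturbation, value``)
or as interval tables (``subject, perturbation, start, end``) that are
expanded to per-timepoint indicators on the right-open interval
``[start, end)``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Subject, TimeSeriesSet, taxon_index
from .inference import FitResult
from .params import ALRParams, CLVParams, GLVParams, LinearParams

FORMAT_VERSION = 1

_LONG_COLS = ["subject", "time", "taxon", "value"]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_dataset(
    path,
    value_kind: str,
    perturbations=None,
    perturbation_names=None,
) -> TimeSeriesSet:
    """Read a delimited abundance table (long or wide; auto-detected).

    ``perturbations`` may be a path to a schedule table.  Counts are
    validated as nonnegative integers; relative abundances must sum to
    one per observation.  Duplicated (subject, time, taxon) cells,
    missing cells and non-increasing times are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if set(_LONG_COLS).issubset(df.columns):
        dup = df.duplicated(subset=["subject", "time", "taxon"])
        if dup.any():
            raise ValueError(
                f"{path}: duplicate (subject, time, taxon) rows:\n"
                f"{df[dup].head().to_string(index=False)}"
            )
        wide = df.pivot(index=["subject", "time"], columns="taxon", values="value")
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index.tolist()[:5]
            raise ValueError(f"{path}: missing cells at (subject, time) {missing}")
        taxa = list(wide.columns)
        subjects_raw = {}
        for (subj, time), row in wide.iterrows():
            subjects_raw.setdefault(subj, []).append((float(time), row.values))
        order = list(dict.fromkeys(df["subject"]))
        blocks = {}
        for subj in order:
            pairs = sorted(subjects_raw[subj], key=lambda p: p[0])
            times = np.array([p[0] for p in pairs])
            blocks[subj] = (times, np.array([p[1] for p in pairs]))
    else:
        meta = [c for c in ("subject", "time") if c in df.columns]
        if meta != ["subject", "time"]:
            raise ValueError(
                f"{path}: expected either long columns {_LONG_COLS} or wide "
                "columns 'subject', 'time', <taxa...>"
            )
        taxa = [c for c in df.columns if c not in ("subject", "time")]
        if df[taxa].isna().any().any():
            raise ValueError(f"{path}: missing cells in wide table")
        if df.duplicated(subset=["subject", "time"]).any():
            raise ValueError(f"{path}: duplicate (subject, time) rows")
        blocks = {}
        for subj, grp in df.groupby("subject", sort=False):
            times = grp["time"].to_numpy(dtype=float)
            if np.any(np.diff(times) <= 0):
                bad = grp.index[1:][np.diff(times) <= 0].tolist()
                raise ValueError(
                    f"{path}: times not strictly increasing for subject "
                    f"{subj!r} (rows {bad})"
                )
            blocks[subj] = (times, grp[taxa].to_numpy(dtype=float))

    sched = _read_schedule(perturbations) if perturbations is not None else None
    if sched is not None:
        p_names = sorted(sched["perturbation"].unique())
    else:
        p_names = list(perturbation_names or [])

    subjects = []
    for subj, (times, values) in blocks.items():
        u = np.zeros((times.size, len(p_names)))
        if sched is not None:
            u = _expand_schedule(sched, str(subj), times, p_names)
        subjects.append(Subject(str(subj), times, values, u))
    return TimeSeriesSet(
        subjects=subjects,
        taxon_names=[str(t) for t in taxa],
        perturbation_names=[str(p) for p in p_names],
        value_kind=value_kind,
    )


def _read_schedule(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    long_cols = {"subject", "time", "perturbation", "value"}
    interval_cols = {"subject", "perturbation", "start", "end"}
    if long_cols.issubset(df.columns):
        df["kind"] = "long"
        return df
    if interval_cols.issubset(df.columns):
        df["kind"] = "interval"
        return df
    raise ValueError(
        f"{path}: schedule needs columns {sorted(long_cols)} or "
        f"{sorted(interval_cols)}"
    )


def _expand_schedule(sched, subject: str, times, p_names) -> np.ndarray:
    u = np.zeros((times.size, len(p_names)))
    rows = sched[sched["subject"].astype(str) == subject]
    for _, row in rows.iterrows():
        p = p_names.index(row["perturbation"])
        if row["kind"] == "long":
            match = np.isclose(times, float(row["time"]))
            if not match.any():
                raise ValueError(
                    f"schedule time {row['time']} not observed for {subject!r}"
                )
            u[match, p] = float(row["value"])
        else:
            u[(times >= float(row["start"])) & (times < float(row["end"])), p] = 1.0
    if not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("perturbation indicators must be 0/1")
    return u


def write_dataset(dataset: TimeSeriesSet, path, schedule_path=None) -> None:
    """Write a dataset as a long-format table (and optionally its schedule)."""
    path = Path(path)
    rows = []
    for s in dataset.subjects:
        for k, t in enumerate(s.times):
            for j, name in enumerate(dataset.taxon_names):
                rows.append((s.subject_id, t, name, s.values[k, j]))
    pd.DataFrame(rows, columns=_LONG_COLS).to_csv(
        path, sep=_sep_for(path), index=False
    )
    if schedule_path is not None and dataset.n_perturbations:
        srows = []
        for s in dataset.subjects:
            for k, t in enumerate(s.times):
                for p, name in enumerate(dataset.perturbation_names):
                    srows.append((s.subject_id, t, name, int(s.perturbations[k, p])))
        pd.DataFrame(
            srows, columns=["subject", "time", "perturbation", "value"]
        ).to_csv(schedule_path, sep=_sep_for(schedule_path), index=False)


_KIND_BY_TYPE = {
    GLVParams: "glv",
    CLVParams: "clv",
    ALRParams: "alr",
    LinearParams: "linear",
}


def write_params(
    obj,
    path,
    taxon_names=None,
    perturbation_names=None,
    seed=None,
) -> None:
    """Serialize fitted or ground-truth parameters to JSON (lossless)."""
    fit = obj if isinstance(obj, FitResult) else None
    params = fit.params if fit is not None else obj
    kind = _KIND_BY_TYPE[type(params)]
    D, P = params.n_taxa, params.n_perturbations
    taxon_names = list(taxon_names or [f"taxon_{i}" for i in range(D)])
    perturbation_names = list(
        perturbation_names or [f"perturbation_{p}" for p in range(P)]
    )
    if len(taxon_names) != D or len(perturbation_names) != P:
        raise ValueError("name lists do not match parameter dimensions")
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": kind,
        "taxon_names": taxon_names,
        "perturbation_names": perturbation_names,
        "seed": seed,
    }
    if kind in ("clv", "alr"):
        payload.update(
            denominator=taxon_names[params.denominator],
            g=params.g_rel.tolist(),
            A=params.A_rel.tolist(),
            B=params.B_rel.tolist(),
        )
    else:
        payload.update(g=params.g.tolist(), A=params.A.tolist(), B=params.B.tolist())
    if fit is not None:
        payload["regularization"] = fit.regularization
        payload["objective"] = fit.objective
        payload["n_rows"] = fit.n_rows
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_params(path):
    """Load a parameter JSON file written by :func:`write_params`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported parameter file version: {version!r}")
    kind = payload["kind"]
    g = np.asarray(payload["g"], dtype=float)
    A = np.asarray(payload["A"], dtype=float)
    B = np.asarray(payload["B"], dtype=float)
    names = payload["taxon_names"]
    if kind == "glv":
        params = GLVParams(g, A, B)
    elif kind == "linear":
        params = LinearParams(g, A, B)
    else:
        den = taxon_index(names, payload["denominator"])
        cls = CLVParams if kind == "clv" else ALRParams
        params = cls(g, A, B, denominator=den)
    if params.n_taxa != len(names):
        raise ValueError("taxon names do not match parameter dimensions")
    return params, payload


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logs."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
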