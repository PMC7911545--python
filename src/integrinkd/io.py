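"""CSV interchange, result serialization, and the end-to-end pipeline.

File formats (comma-separated, UTF-8, ``.`` decimal separator, mandatory
header row):

* Detachment counts, long form:
  ``q_percent, replicate_id, round_index, pressure_atm, cells_remaining``
  with round 0 carrying the initial count at pressure 0.
* Per-cell table: ``cell_id, x_um, y_um, round_detached`` (empty = never).
* Kinetic traces, long form: ``well_id, q_percent, time_s, shift_pm``.

``run_pipeline`` chains the stages: coating composition -> ligand density
-> detachment curves -> histograms -> W -> KMAL fit -> molar conversion
(micropipette mode), or traces -> logistic fits -> plateau profile -> KMAL
fit -> molar conversion (biosensor mode).  All results are returned as a
JSON-serializable dict carrying a schema version and the effective
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detachment as da
from .binding import ConfinementModel, fit_kmal, kd_2d_to_3d
from .detachment import ConditionDataset, PressureSchedule, ReplicateCounts
from .errors import InvalidDataError
from .kinetics import KineticTrace, fit_logistic, lambda_max_profile
from .surface import PolymerSpec, rgd_density

log = logging.getLogger("integrinkd")

SCHEMA_VERSION = "1"

DETACHMENT_COLUMNS = ["q_percent", "replicate_id", "round_index", "pressure_atm", "cells_remaining"]
KINETIC_COLUMNS = ["well_id", "q_percent", "time_s", "shift_pm"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a pipeline run."""

    polymer: PolymerSpec = field(default_factory=PolymerSpec)
    lc_nm: float = 100.0
    mode: str = "averaged"  # averaged | pooled (micropipette curves)
    weighted: bool = False
    baseline_end_s: float | None = None


# ---------------------------------------------------------------------------
# CSV readers / writers


def write_detachment_csv(path, datasets: list[ConditionDataset]) -> None:
    rows = []
    for ds in datasets:
        for rep_id, rep in enumerate(ds.replicates):
            rows.append((ds.q, rep_id, 0, 0.0, rep.initial))
            for n, (p, c) in enumerate(zip(ds.schedule.pressures, rep.remaining), start=1):
                rows.append((ds.q, rep_id, n, p, c))
    pd.DataFrame(rows, columns=DETACHMENT_COLUMNS).to_csv(path, index=False)


def read_detachment_csv(path) -> list[ConditionDataset]:
    """Read and validate a long-form detachment counts file.

    Raises :class:`InvalidDataError` naming the offending rows for schema
    mismatches, negative or non-monotone counts, or an empty file.
    """
    df = _read_csv(path, DETACHMENT_COLUMNS)
    datasets = []
    for q, group in df.groupby("q_percent", sort=True):
        schedule = None
        reps = []
        for rep_id, rep_rows in group.groupby("replicate_id", sort=True):
            rep_rows = rep_rows.sort_values("round_index")
            rounds = rep_rows["round_index"].to_numpy()
            if rounds[0] != 0 or not np.array_equal(rounds, np.arange(len(rounds))):
                raise InvalidDataError(
                    f"q={q} replicate {rep_id}: round_index must run 0..N "
                    f"(file rows {_rownums(rep_rows)})"
                )
            pressures = tuple(rep_rows["pressure_atm"].to_numpy()[1:])
            sched = PressureSchedule(pressures=pressures)
            if schedule is None:
                schedule = sched
            elif sched.pressures != schedule.pressures:
                raise InvalidDataError(
                    f"q={q} replicate {rep_id}: pressure schedule differs from "
                    f"other replicates (file rows {_rownums(rep_rows)})"
                )
            counts = rep_rows["cells_remaining"].to_numpy()
            bad = np.nonzero((counts < 0) | (counts != counts.astype(int)))[0]
            if bad.size:
                raise InvalidDataError(
                    f"q={q} replicate {rep_id}: negative or non-integer counts "
                    f"(file rows {_rownums(rep_rows.iloc[bad])})"
                )
            increases = np.nonzero(np.diff(counts) > 0)[0]
            if increases.size:
                raise InvalidDataError(
                    f"q={q} replicate {rep_id}: cells_remaining increases at "
                    f"round {increases[0] + 1} (file row "
                    f"{_rownums(rep_rows.iloc[increases + 1])})"
                )
            reps.append(
                ReplicateCounts(initial=int(counts[0]), remaining=tuple(int(c) for c in counts[1:]))
            )
        datasets.append(ConditionDataset(q=float(q), schedule=schedule, replicates=tuple(reps)))
    return datasets


def write_cell_table_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_cell_table_csv(path) -> pd.DataFrame:
    df = _read_csv(path, list(da.CELL_TABLE_COLUMNS))
    if df["cell_id"].duplicated().any():
        dup = df[df["cell_id"].duplicated()]
        raise InvalidDataError(f"duplicate cell_id values (file rows {_rownums(dup)})")
    return df


def write_kinetics_csv(path, traces: list[KineticTrace]) -> None:
    rows = [
        (tr.well_id, tr.q, t, s)
        for tr in traces
        for t, s in zip(tr.times, tr.shifts)
    ]
    pd.DataFrame(rows, columns=KINETIC_COLUMNS).to_csv(path, index=False)


def read_kinetics_csv(path) -> list[KineticTrace]:
    df = _read_csv(path, KINETIC_COLUMNS)
    traces = []
    for (well, q), g in df.groupby(["well_id", "q_percent"], sort=True):
        g = g.sort_values("time_s")
        traces.append(
            KineticTrace(
                times=g["time_s"].to_numpy(float),
                shifts=g["shift_pm"].to_numpy(float),
                q=float(q),
                well_id=str(well),
            )
        )
    return traces


def _read_csv(path, expected_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidDataError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise InvalidDataError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise InvalidDataError(f"{path}: no data rows")
    # 1-based file row numbers (header is row 1)
    df.index = df.index + 2
    return df


def _rownums(rows: pd.DataFrame) -> str:
    return ", ".join(str(i) for i in rows.index.tolist())


# ---------------------------------------------------------------------------
# Pipeline


def analyze_detachment(
    datasets: list[ConditionDataset], config: RunConfig
) -> tuple[dict, list[tuple[float, da.DetachmentHistogram]], np.ndarray, np.ndarray, np.ndarray]:
    """Per-condition curves, histograms, W and subpopulations.

    Returns the per-condition summary dict plus the (rho, histogram) pairs
    and the (l0, W, W_se) arrays consumed by the KMAL fit.
    """
    per_condition = {}
    hists = []
    l0, w, w_se = [], [], []
    for ds in sorted(datasets, key=lambda d: d.q):
        rho = rgd_density(dataclasses.replace(config.polymer, q=ds.q)).rho_number
        if config.mode == "pooled":
            curve = da.remaining_fraction_pooled(ds)
        else:
            curve = da.remaining_fraction_averaged(ds)
        hist = da.build_histogram(curve, ds.schedule)
        W = da.weighted_average(hist)
        sub = da.subpopulations(hist)
        hists.append((rho, hist))
        l0.append(rho)
        w.append(W)
        w_se.append(_w_stderr(ds))
        per_condition[f"q={ds.q:g}"] = {
            "rho_number_per_um2": rho,
            "W_atm": W,
            "weak": sub.weak,
            "moderate": sub.moderate,
            "strong": sub.strong,
        }
    return per_condition, hists, np.array(l0), np.array(w), np.array(w_se)


def _w_stderr(ds: ConditionDataset) -> float:
    """Standard error of W across replicates (nan for a single replicate)."""
    if len(ds.replicates) < 2:
        return float("nan")
    ws = []
    for rep in ds.replicates:
        single = ConditionDataset(q=ds.q, schedule=ds.schedule, replicates=(rep,))
        curve = da.remaining_fraction_averaged(single)
        ws.append(da.weighted_average(da.build_histogram(curve, ds.schedule)))
    return float(np.std(ws, ddof=1) / np.sqrt(len(ws)))


def run_pipeline(
    config: RunConfig,
    detachment_datasets: list[ConditionDataset] | None = None,
    kinetic_traces: list[KineticTrace] | None = None,
) -> dict:
    """Run the full analysis in micropipette and/or biosensor mode.

    Exactly the stages applicable to the supplied inputs are executed; the
    returned dict is JSON-serializable and carries the schema version and
    the effective configuration.
    """
    if detachment_datasets is None and kinetic_traces is None:
        raise InvalidDataError("no inputs: supply detachment datasets and/or kinetic traces")
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "polymer": dataclasses.asdict(config.polymer),
            "lc_nm": config.lc_nm,
            "mode": config.mode,
            "weighted": config.weighted,
            "baseline_end_s": config.baseline_end_s,
        },
    }
    model = ConfinementModel(lc=config.lc_nm)

    if detachment_datasets is not None:
        log.info("micropipette mode: %d conditions", len(detachment_datasets))
        per_condition, hists, l0, w, w_se = analyze_detachment(detachment_datasets, config)
        se = w_se if (config.weighted and np.all(np.isfinite(w_se)) and np.all(w_se > 0)) else None
        fit = fit_kmal(l0, w, response_se=se)
        molar = kd_2d_to_3d(fit.kd_2d, fit.se_kd_2d, model)
        hm = da.heatmap(hists)
        summary["micropipette"] = {
            "per_condition": per_condition,
            "heatmap": {
                "rho_number_per_um2": hm.rho_numbers.tolist(),
                "bin_edges_atm": hm.bin_edges.tolist(),
                "values": hm.values.tolist(),
            },
            **_fit_summary(fit, molar, config.lc_nm),
        }

    if kinetic_traces is not None:
        log.info("biosensor mode: %d traces", len(kinetic_traces))
        summary["rwg"] = _rwg_summary(kinetic_traces, config, model)
    return summary


def _rwg_summary(traces: list[KineticTrace], config: RunConfig, model: ConfinementModel) -> dict:
    per_well = {}
    by_q: dict[float, list] = {}
    for tr in traces:
        if config.baseline_end_s is not None:
            tr = tr.baseline_corrected(config.baseline_end_s)
        lf = fit_logistic(tr)
        per_well[tr.well_id or f"q={tr.q:g}"] = {
            "q_percent": tr.q,
            "r_per_s": lf.r,
            "lambda_max_pm": lf.lambda_max,
            "lambda_0_pm": lf.lambda_0,
            "se_lambda_max_pm": lf.se_lambda_max,
            "residual_rms_pm": lf.residual_rms,
            "flags": list(lf.flags),
        }
        by_q.setdefault(tr.q, []).append(lf)
    profile = []
    for q, fits in sorted(by_q.items()):
        rho = rgd_density(dataclasses.replace(config.polymer, q=q)).rho_number
        lams = np.array([f.lambda_max for f in fits])
        se = (
            float(np.std(lams, ddof=1) / np.sqrt(len(lams)))
            if len(lams) >= 2
            else float(fits[0].se_lambda_max)
        )
        mean_fit = dataclasses.replace(fits[0], lambda_max=float(lams.mean()), se_lambda_max=se)
        profile.append((rho, mean_fit))
    l0, resp, resp_se = lambda_max_profile(profile)
    use_se = resp_se if (config.weighted and np.all(np.isfinite(resp_se)) and np.all(resp_se > 0)) else None
    fit = fit_kmal(l0, resp, response_se=use_se)
    molar = kd_2d_to_3d(fit.kd_2d, fit.se_kd_2d, model)
    return {
        "per_well": per_well,
        "profile": {
            "rho_number_per_um2": l0.tolist(),
            "lambda_max_pm": resp.tolist(),
            "lambda_max_se_pm": resp_se.tolist(),
        },
        **_fit_summary(fit, molar, model.lc),
    }


def _fit_summary(fit, molar, lc_nm: float) -> dict:
    return {
        "i0": fit.i0,
        "kd_2d_per_um2": fit.kd_2d,
        "se_kd_2d": fit.se_kd_2d,
        "kd_3d_uM": molar.kd_3d,
        "se_kd_3d_uM": molar.se_kd_3d,
        "lc_nm": lc_nm,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "diagnostics": {
            k: v for k, v in fit.diagnostics.items() if k != "attempts"
        },
    }


def dump_json(obj: dict, path=None) -> str:
    """Serialize results deterministically (sorted keys, repr-exact floats)."""
    text = json.dumps(obj, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
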