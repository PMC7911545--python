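"""Synthetic assay data with a known ground-truth dissociation constant.

No public detachment or biosensor dataset accompanies the assay design, so
every downstream stage is validated by parameter recovery on simulated
data.  The generative model mirrors the assumption the inference itself
makes — adhesion strength proportional to the bound-ligand fraction
s = rho / (rho + Kd2D):

* Micropipette mode: each cell draws a critical detachment pressure from a
  lognormal whose median is ``alpha * s`` with dispersion ``sigma_cell``.
  A fixed ``weak_floor`` fraction of cells instead draws from the
  weakest-condition component regardless of density, emulating the
  persistently weak-adhering subpopulation seen at every ligand density.
  Per-round remaining counts are obtained by thresholding the critical
  pressures against the pressure schedule, so counts are monotone by
  construction.
* Biosensor mode: per condition the logistic plateau is
  ``rwg_lambda_sat * s`` and each well's trace is the closed-form logistic
  solution plus iid Gaussian noise.

Everything is reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detachment import (
    CELL_TABLE_COLUMNS,
    ConditionDataset,
    PressureSchedule,
    ReplicateCounts,
)
from .errors import InvalidParameterError
from .kinetics import KineticTrace, logistic_solution
from .surface import PolymerSpec, rgd_density

#: PPR:PP mixing ratios used across the assay design, percent.
DEFAULT_Q_VALUES = (1.0, 2.0, 3.0, 5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and nuisance parameters of the simulated experiments.

    ``alpha`` (atm) maps the bound-ligand fraction to the median critical
    pressure of the adherent component; ``sigma_cell`` is the lognormal
    dispersion of critical pressures within a component; ``weak_floor`` is
    the density-independent weakly-adhering fraction.  Defaults follow the
    assay design: 8 mixing ratios, 3 replicates of 110 detected cells, a
    6-round 0.07-0.22 atm schedule, and 1.5 h biosensor traces sampled
    every 30 s.
    """

    true_kd_2d: float = 4500.0  # 1/um^2
    q_values: tuple[float, ...] = DEFAULT_Q_VALUES
    cells_per_replicate: int = 110
    n_replicates: int = 3
    schedule: PressureSchedule = field(default_factory=PressureSchedule)
    polymer: PolymerSpec = field(default_factory=PolymerSpec)
    alpha: float = 0.25  # atm at full saturation
    sigma_cell: float = 0.2
    weak_floor: float = 0.3
    field_um: float = 1200.0  # side of the square imaging field
    rwg_lambda_sat: float = 300.0  # pm at full saturation
    rwg_r: float = 0.002  # 1/s
    rwg_noise_sd: float = 5.0  # pm
    rwg_duration_s: float = 5400.0
    rwg_step_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_kd_2d > 0:
            raise InvalidParameterError("true_kd_2d must be positive")
        if len(self.q_values) < 1 or any(q <= 0 or q > 100 for q in self.q_values):
            raise InvalidParameterError("q_values must lie in (0, 100]")
        if self.cells_per_replicate < 1 or self.n_replicates < 1:
            raise InvalidParameterError("need at least one cell and one replicate")
        if not self.alpha > 0 or self.sigma_cell < 0:
            raise InvalidParameterError("alpha must be positive, sigma_cell non-negative")
        if not (0.0 <= self.weak_floor < 1.0):
            raise InvalidParameterError("weak_floor must lie in [0, 1)")
        if self.rwg_noise_sd < 0 or not self.rwg_r > 0 or not self.rwg_lambda_sat > 0:
            raise InvalidParameterError("invalid biosensor parameters")
        if not 0 < self.rwg_step_s < self.rwg_duration_s:
            raise InvalidParameterError("invalid biosensor sampling window")

    def saturation(self, q: float) -> float:
        """Bound-ligand fraction s = rho/(rho + Kd2D) at mixing ratio q."""
        rho = rgd_density(replace(self.polymer, q=q)).rho_number
        return rho / (rho + self.true_kd_2d)


def simulate_detachment(
    config: SimulationConfig,
) -> tuple[list[ConditionDataset], list[pd.DataFrame]]:
    """Simulate the micropipette assay for every mixing ratio.

    Returns per-condition count datasets and matching per-cell tables
    (columns ``cell_id, x_um, y_um, round_detached``; ``round_detached`` is
    NaN for cells that never detach).  Identical configs give identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    pressures = np.asarray(config.schedule.pressures)
    s_min = config.saturation(min(config.q_values))
    datasets: list[ConditionDataset] = []
    tables: list[pd.DataFrame] = []
    for q in config.q_values:
        s = config.saturation(q)
        reps = []
        rows = []
        for rep in range(config.n_replicates):
            p_star = _critical_pressures(config, rng, s, s_min)
            remaining = (p_star[None, :] > pressures[:, None]).sum(axis=1)
            reps.append(
                ReplicateCounts(initial=len(p_star), remaining=tuple(int(c) for c in remaining))
            )
            rounds = np.searchsorted(pressures, p_star, side="left") + 1.0
            rounds[p_star > pressures[-1]] = np.nan
            xy = rng.uniform(0.0, config.field_um, size=(len(p_star), 2))
            for i, (x, yy) in enumerate(xy):
                rows.append((f"q{q:g}_r{rep}_c{i}", float(x), float(yy), rounds[i]))
        datasets.append(
            ConditionDataset(q=q, schedule=config.schedule, replicates=tuple(reps))
        )
        tables.append(pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS)))
    return datasets, tables


def _critical_pressures(
    config: SimulationConfig, rng: np.random.Generator, s: float, s_min: float
) -> np.ndarray:
    n = config.cells_per_replicate
    n_weak = rng.binomial(n, config.weak_floor)
    medians = np.concatenate(
        [np.full(n_weak, config.alpha * s_min), np.full(n - n_weak, config.alpha * s)]
    )
    return np.exp(np.log(medians) + config.sigma_cell * rng.standard_normal(n))


def simulate_rwg(config: SimulationConfig) -> list[KineticTrace]:
    """Simulate biosensor wavelength-shift traces for every mixing ratio.

    One trace per (condition, well); ``n_replicates`` wells per condition.
    The plateau follows the saturation law, the initial shift is 2% of the
    plateau, and Gaussian noise of sd ``rwg_noise_sd`` is added pointwise.
    """
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.rwg_duration_s + config.rwg_step_s / 2, config.rwg_step_s)
    traces: list[KineticTrace] = []
    for q in config.q_values:
        lam_max = config.rwg_lambda_sat * config.saturation(q)
        clean = logistic_solution(times, config.rwg_r, lam_max, 0.02 * lam_max)
        for well in range(config.n_replicates):
            noise = config.rwg_noise_sd * rng.standard_normal(times.size)
            traces.append(
                KineticTrace(
                    times=times,
                    shifts=clean + noise,
                    q=q,
                    well_id=f"q{q:g}_w{well}",
                )
            )
    return traces
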