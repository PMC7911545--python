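"""Label-free biosensor adhesion kinetics.

A resonant waveguide grating (RWG) biosensor reports cell adhesion as a
shift of the resonant wavelength (pm).  Adhesion kinetics follow logistic
growth, d(lambda)/dt = r * lambda * (1 - lambda/lambda_max); each trace is
fitted with the closed-form solution of this ODE and the plateau
lambda_max is the steady-state adhesion response passed on to the KMAL
saturation fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidDataError, InvalidParameterError


@dataclass(frozen=True)
class KineticTrace:
    """One well's baseline-corrected wavelength-shift trace."""

    times: np.ndarray  # s, strictly increasing
    shifts: np.ndarray  # pm
    q: float  # percent PPR
    well_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.shifts, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise InvalidDataError("times and shifts must be 1-D arrays of equal length")
        if t.size < 5:
            raise InvalidDataError("a trace needs at least 5 points for fitting")
        if not np.all(np.diff(t) > 0):
            raise InvalidDataError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "shifts", s)

    def baseline_corrected(self, baseline_end_s: float) -> "KineticTrace":
        """Subtract the mean shift over the declared baseline window [t0, baseline_end_s]."""
        mask = self.times <= baseline_end_s
        if not mask.any():
            raise InvalidDataError("baseline window contains no points")
        return KineticTrace(
            times=self.times,
            shifts=self.shifts - float(self.shifts[mask].mean()),
            q=self.q,
            well_id=self.well_id,
        )


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters for one trace."""

    r: float  # 1/s
    lambda_max: float  # pm
    lambda_0: float  # pm
    se_lambda_max: float  # pm
    residual_rms: float  # pm
    flags: tuple[str, ...] = ()


def logistic_solution(t, r: float, lambda_max: float, lambda_0: float):
    """Closed-form logistic curve lambda(t).

    lambda(t) = lambda_max * lambda_0 / (lambda_0 + (lambda_max - lambda_0)
    * exp(-r t)); equals lambda_0 at t = 0 and tends to lambda_max.  Written
    in the decaying-exponential form so large r*t cannot overflow.
    """
    if not r > 0:
        raise InvalidParameterError("rate r must be positive")
    if not (0 < lambda_0 <= lambda_max):
        raise InvalidParameterError("need 0 < lambda_0 <= lambda_max")
    t = np.asarray(t, dtype=float)
    out = lambda_max * lambda_0 / (lambda_0 + (lambda_max - lambda_0) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


def fit_logistic(trace: KineticTrace) -> LogisticFit:
    """Fit the logistic solution to a wavelength-shift trace.

    Positivity is enforced on all three parameters.  Starting values are
    deterministic: lambda_max from 1.05x the largest shift, lambda_0 from
    the first positive shift (floored at 1% of lambda_max so that noisy,
    even negative, early samples never break the parametrization), and r
    from the early-phase log-slope.  A fit whose plateau exceeds the
    largest observed shift by more than 50% is flagged
    ``plateau unresolved``.
    """
    t = trace.times
    y = trace.shifts
    if np.allclose(y, y[0]):
        raise InvalidDataError("constant trace: nothing to fit")

    ymax = float(y.max())
    if ymax <= 0:
        raise InvalidDataError("trace never rises above zero")
    lam_max0 = 1.05 * ymax
    first_pos = y[y > 0]
    lam00 = max(float(first_pos[0]), 0.01 * lam_max0)
    r0 = _initial_rate(t, y, lam_max0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        r, lam_max, lam0 = theta
        lam0 = min(lam0, lam_max)  # keep the closed form in its domain
        return lam_max * lam0 / (lam0 + (lam_max - lam0) * np.exp(-r * t)) - y

    lower = np.array([1e-12, 1e-12, 1e-12])
    x0 = np.array([r0, lam_max0, lam00])
    sol = least_squares(residuals, x0, bounds=(lower, np.inf))
    if not sol.success:
        sol = least_squares(residuals, np.array([r0 * 0.1, lam_max0, lam00]), bounds=(lower, np.inf))
    if not sol.success:
        raise FitFailureError(
            "logistic fit did not converge", {"status": sol.status, "message": sol.message}
        )
    r_hat, lam_max_hat, lam0_hat = sol.x
    dof = max(t.size - 3, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se_lam_max = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_lam_max = float("nan")
    flags = []
    if lam_max_hat > 1.5 * ymax:
        flags.append("plateau unresolved")
    return LogisticFit(
        r=float(r_hat),
        lambda_max=float(lam_max_hat),
        lambda_0=float(min(lam0_hat, lam_max_hat)),
        se_lambda_max=se_lam_max,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        flags=tuple(flags),
    )


def _initial_rate(t: np.ndarray, y: np.ndarray, lam_max0: float) -> float:
    """Early-phase exponential growth rate from the log-slope of the rising part."""
    mask = (y > 0) & (y < 0.5 * lam_max0)
    if mask.sum() >= 2:
        tt, yy = t[mask], np.log(y[mask])
        slope = np.polyfit(tt, yy, 1)[0]
        if slope > 0:
            return float(slope)
    span = t[-1] - t[0]
    return 5.0 / span if span > 0 else 1e-3


def lambda_max_profile(
    fits: Sequence[tuple[float, LogisticFit]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrange per-condition plateaus as a saturation profile.

    Takes (rho_number, LogisticFit) pairs and returns density-sorted arrays
    (l0, response, response_se) ready for the KMAL fit.
    """
    if len(fits) < 3:
        raise InvalidDataError("KMAL fitting downstream needs at least 3 conditions")
    order = np.argsort([rho for rho, _ in fits], kind="stable")
    l0 = np.array([fits[i][0] for i in order], dtype=float)
    resp = np.array([fits[i][1].lambda_max for i in order], dtype=float)
    se = np.array([fits[i][1].se_lambda_max for i in order], dtype=float)
    return l0, resp, se
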