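"""Equilibrium binding inference.

Fits the steady-state kinetic mass action law (KMAL)

    B(L0) = L0 * I0 / (L0 + Kd2D)

to pairs of (ligand surface density L0, adhesion response), where the
response is any quantity proportional to the number of bound ligands: the
weighted-average detachment pressure W of the micropipette assay, or the
plateau wavelength shift lambda_max of the biosensor assay.  The fitted
two-dimensional dissociation constant Kd2D (1/um^2) is the ligand density
at half-saturation; division by the confinement-zone thickness l_c (the
cell-substrate separation, default 100 nm) converts it into a molar
three-dimensional constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidDataError, InvalidParameterError
from .surface import AVOGADRO


@dataclass(frozen=True)
class BindingFit:
    """Result of a KMAL saturation fit.

    ``i0`` is the response amplitude (same units as the response: atm for W,
    pm for lambda_max); ``kd_2d`` is in 1/um^2.  Standard errors come from
    the Jacobian at the optimum scaled by the residual variance.
    """

    i0: float
    kd_2d: float
    se_i0: float
    se_kd_2d: float
    covariance: np.ndarray
    residuals: np.ndarray
    n_points: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConfinementModel:
    """Thickness of the interfacial confinement zone, nm.

    The default 100 nm corresponds to the typical separation between the
    cell membrane and the substrate.
    """

    lc: float = 100.0

    def __post_init__(self) -> None:
        if not self.lc > 0:
            raise InvalidParameterError("confinement thickness lc must be positive")


@dataclass(frozen=True)
class MolarKd:
    """Molar (3D) dissociation constant with its propagated standard error, uM."""

    kd_3d: float
    se_kd_3d: float


def kmal_response(l0, i0: float, kd_2d: float):
    """Saturation response B = L0*I0/(L0 + Kd2D); i0/2 at L0 = Kd2D."""
    l0 = np.asarray(l0, dtype=float)
    out = l0 * i0 / (l0 + kd_2d)
    return float(out) if out.ndim == 0 else out


def fit_kmal(
    l0,
    response,
    response_se=None,
) -> BindingFit:
    """Least-squares fit of the KMAL saturation curve.

    Parameters
    ----------
    l0 : array-like
        Ligand surface densities, 1/um^2; non-negative, at least two
        distinct positive values.
    response : array-like
        Adhesion responses, one per density.
    response_se : array-like, optional
        Per-point standard errors; when given, the fit is weighted by
        1/se^2.

    Notes
    -----
    Both parameters are constrained positive.  The starting point is
    deterministic and scale-free (kd0 = median positive density,
    i0_0 = 1.1 x max response); on failure the solver restarts from kd0
    scaled by {0.1, 10} and i0_0 scaled by {0.5, 2}.  Flat response data
    leave Kd2D unidentifiable: the estimate is driven to its lower bound
    and the fit is flagged ``saturated`` in the diagnostics.
    """
    l0 = np.asarray(l0, dtype=float)
    y = np.asarray(response, dtype=float)
    if l0.shape != y.shape or l0.ndim != 1:
        raise InvalidDataError("l0 and response must be 1-D arrays of equal length")
    if l0.size < 3:
        raise InvalidDataError("KMAL fit needs at least 3 points")
    if np.any(l0 < 0):
        raise InvalidDataError("ligand densities must be non-negative")
    positive = l0[l0 > 0]
    if np.unique(positive).size < 2:
        raise InvalidDataError("need at least 2 distinct positive ligand densities")
    weights = None
    if response_se is not None:
        se = np.asarray(response_se, dtype=float)
        if se.shape != y.shape or np.any(se <= 0):
            raise InvalidDataError("response_se must be positive and match response")
        weights = 1.0 / se

    def residuals(theta: np.ndarray) -> np.ndarray:
        r = theta[0] * l0 / (l0 + theta[1]) - y
        return r * weights if weights is not None else r

    kd0 = float(np.median(positive))
    i00 = 1.1 * float(np.max(y))
    if not i00 > 0:
        i00 = 1.0
    lower = np.array([1e-12, 1e-12])
    starts = [(i00, kd0)] + [
        (i00 * fi, kd0 * fk) for fk in (0.1, 10.0) for fi in (1.0, 0.5, 2.0)
    ]
    best = None
    tried = []
    for start in starts[:7]:
        sol = least_squares(residuals, np.asarray(start), bounds=(lower, np.inf))
        tried.append({"start": start, "status": sol.status, "cost": float(sol.cost)})
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.success:
            break
    if best is None or not best.success:
        raise FitFailureError("KMAL fit did not converge", {"attempts": tried})

    i0_hat, kd_hat = best.x
    dof = max(l0.size - 2, 1)
    res_unweighted = i0_hat * l0 / (l0 + kd_hat) - y
    s2 = float(np.sum(best.fun**2)) / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se_i0, se_kd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        se_i0 = se_kd = float("nan")
    diagnostics = {"attempts": tried, "cost": float(best.cost)}
    if kd_hat < 1e-3 * float(np.min(positive)):
        diagnostics["saturated"] = "Kd not identifiable: response flat in ligand density"
    return BindingFit(
        i0=float(i0_hat),
        kd_2d=float(kd_hat),
        se_i0=float(se_i0),
        se_kd_2d=float(se_kd),
        covariance=cov,
        residuals=res_unweighted,
        n_points=int(l0.size),
        converged=True,
        diagnostics=diagnostics,
    )


def kd_2d_to_3d(kd_2d: float, se_kd_2d: float, model: ConfinementModel | None = None) -> MolarKd:
    """Convert a 2D dissociation constant to its molar 3D equivalent.

    Dividing the areal density Kd2D (1/um^2) by the confinement thickness
    l_c gives a volumetric density (1/um^3); multiplying by 1e15 um^3/L and
    dividing by Avogadro's number yields mol/L, reported in uM.  The
    standard error propagates by the same linear factor, so the relative
    error is preserved exactly.
    """
    model = model or ConfinementModel()
    if not kd_2d > 0:
        raise InvalidParameterError("kd_2d must be positive")
    if se_kd_2d < 0:
        raise InvalidParameterError("se_kd_2d must be non-negative")
    lc_um = model.lc / 1000.0
    factor = (1.0 / lc_um) * 1e15 / AVOGADRO * 1e6  # (1/um^2 -> uM)
    return MolarKd(kd_3d=kd_2d * factor, se_kd_3d=se_kd_2d * factor)
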