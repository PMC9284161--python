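"""Inverse solves and the drying sweep.

Mirrors the study's fitting logic: the passive-layer (sclerenchyma) modulus
is the one material parameter that could only be bounded experimentally, so
it is identified by requiring the fully dry forward model to reach the
measured dry-state angular change; the active-layer contraction over the
80 -> 30 % rh interval is identified the same way from the measured interval
angle.  Both are scalar bracketed root finds on a forward map that is first
checked to be monotone over the bracket (non-monotone maps are refused, not
silently solved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, DomainError
from .geometry import ScaleModel
from .materials import DryingPath, MaterialCurve, TissueMaterial, young_modulus, xi_from_rh
from .mechanics import TissueState, bend_scale

__all__ = [
    "CalibrationResult",
    "IntervalPrediction",
    "fit_passive_modulus",
    "fit_contraction",
    "drying_sweep",
    "predict_interval_angle",
    "DEFAULT_E_BRACKET",
    "DEFAULT_EPS_BRACKET",
]

DEFAULT_E_BRACKET = (100.0, 5000.0)  # MPa
DEFAULT_EPS_BRACKET = (0.0, 0.22)  # contraction increment, dimensionless
TOL_DEG = 1e-4
MAX_ITER = 200
_MONOTONE_PROBES = 9


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one scalar inverse solve."""

    parameter_name: str
    fitted_value: float
    residual_deg: float
    bracket: tuple[float, float]
    iterations: int
    converged: bool

    def __str__(self) -> str:  # key=value report used by the CLI
        return (
            f"parameter={self.parameter_name} value={self.fitted_value:.6g} "
            f"residual_deg={self.residual_deg:.3g} "
            f"bracket=({self.bracket[0]:g},{self.bracket[1]:g}) "
            f"iterations={self.iterations} converged={self.converged}"
        )


def _check_monotone(f: Callable[[float], float], lo: float, hi: float,
                    what: str) -> tuple[float, float]:
    xs = np.linspace(lo, hi, _MONOTONE_PROBES)
    ys = np.array([f(x) for x in xs])
    d = np.diff(ys)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise CalibrationError(
            f"forward map for {what} is not monotone over the bracket "
            f"[{lo:g}, {hi:g}]; refusing to root-find "
            f"(gamma at probes: {np.round(ys, 4).tolist()})"
        )
    return float(ys[0]), float(ys[-1])


def _bisect(f: Callable[[float], float], lo: float, hi: float, flo: float,
            fhi: float, *, tol_deg: float, max_iter: int,
            what: str) -> tuple[float, float, int]:
    """Bracketed bisection on the residual; returns (root, residual, iters).

    The bracket is shrunk until it is relatively tiny, which makes the
    fitted parameter reproducible far below the angular tolerance (round
    trips close to machine precision); ``tol_deg`` defines *convergence*
    of the residual, not the stopping width.
    """
    if flo == 0.0:
        return lo, 0.0, 0
    if fhi == 0.0:
        return hi, 0.0, 0
    if np.sign(flo) == np.sign(fhi):
        raise CalibrationError(
            f"no sign change over bracket for {what}: "
            f"gamma(lo)-target={flo:g} deg, gamma(hi)-target={fhi:g} deg"
        )
    it = 0
    fmid = np.inf
    mid = 0.5 * (lo + hi)
    width_tol = 1e-13 * max(abs(lo), abs(hi), 1.0)
    while it < max_iter and (hi - lo) > width_tol:
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        it += 1
        if fmid == 0.0:
            break
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi, fhi = mid, fmid
    return mid, float(fmid), it


def fit_passive_modulus(
    model: ScaleModel,
    target_gamma_deg: float = 24.4,
    eps_active: float = -0.22,
    e_active: float = 37.0,
    bracket: tuple[float, float] = DEFAULT_E_BRACKET,
    *,
    tol_deg: float = TOL_DEG,
    max_iter: int = MAX_ITER,
) -> CalibrationResult:
    """Identify the passive-layer modulus from the dry-state angle.

    Root-find on E_passive so that the forward model with the given active
    contraction and active modulus reaches ``target_gamma_deg``.  On the
    physically relevant stiff branch (E_passive well above E_active) the
    angle decreases monotonically with E_passive, which is verified before
    solving.
    """
    def f(e_passive: float) -> float:
        state = TissueState(e_active=e_active, e_passive=e_passive,
                            eps_active=eps_active)
        return bend_scale(model, state).gamma_deg - target_gamma_deg

    lo, hi = float(bracket[0]), float(bracket[1])
    flo, fhi = _check_monotone(f, lo, hi, "passive modulus")
    root, resid, it = _bisect(f, lo, hi, flo, fhi, tol_deg=tol_deg,
                              max_iter=max_iter, what="passive modulus")
    return CalibrationResult(
        parameter_name="e_passive",
        fitted_value=root,
        residual_deg=resid,
        bracket=(float(bracket[0]), float(bracket[1])),
        iterations=it,
        converged=abs(resid) <= tol_deg,
    )


def fit_contraction(
    model: ScaleModel,
    target_gamma_deg: float,
    endpoint_states: tuple[tuple[float, float], tuple[float, float]],
    eps_start: float = 0.0,
    bracket: tuple[float, float] = DEFAULT_EPS_BRACKET,
    *,
    tol_deg: float = TOL_DEG,
    max_iter: int = MAX_ITER,
) -> CalibrationResult:
    """Identify the contraction increment producing a measured interval angle.

    Parameters
    ----------
    endpoint_states
        ``((E_passive_A, E_active_A), (E_passive_B, E_active_B))`` -- moduli
        at the start (wetter) and end (drier) of the humidity interval.
    eps_start
        Signed active eigenstrain already present in state A (0 for the wet
        reference; the drying-path value when the interval starts part-way
        along the path).
    bracket
        Range of the (non-negative) contraction *increment* d; state B has
        eigenstrain ``eps_start - d``.
    """
    (e_p_a, e_a_a), (e_p_b, e_a_b) = endpoint_states
    state_a = TissueState(e_active=e_a_a, e_passive=e_p_a, eps_active=eps_start)
    gamma_a = bend_scale(model, state_a).gamma_deg

    def f(d: float) -> float:
        state_b = TissueState(e_active=e_a_b, e_passive=e_p_b,
                              eps_active=eps_start - d)
        return (bend_scale(model, state_b).gamma_deg - gamma_a) - target_gamma_deg

    lo, hi = float(bracket[0]), float(bracket[1])
    flo, fhi = _check_monotone(f, lo, hi, "contraction increment")
    root, resid, it = _bisect(f, lo, hi, flo, fhi, tol_deg=tol_deg,
                              max_iter=max_iter, what="contraction increment")
    return CalibrationResult(
        parameter_name="contraction_increment",
        fitted_value=root,
        residual_deg=resid,
        bracket=(lo, hi),
        iterations=it,
        converged=abs(resid) <= tol_deg,
    )


def _state_on_path(path: DryingPath, xi: float,
                   active_curve: MaterialCurve | TissueMaterial,
                   passive_curve: MaterialCurve | TissueMaterial) -> TissueState:
    """Tissue state at drying coordinate xi.

    The passive modulus follows the path's linear law; the active modulus is
    read from its humidity curve at the rh equivalent of the current passive
    modulus (clamped where the path exceeds the measured curve range).
    """
    e_p = path.passive_modulus(xi)
    curve = passive_curve.curve if isinstance(passive_curve, TissueMaterial) else passive_curve
    rh_equiv = curve.rh_at_modulus(e_p)
    e_a = young_modulus(active_curve, rh_equiv)
    return TissueState(e_active=e_a, e_passive=e_p,
                       eps_active=path.active_strain(xi))


def drying_sweep(
    model: ScaleModel,
    path: DryingPath,
    n_points: int = 51,
    *,
    active_curve: MaterialCurve | TissueMaterial | None = None,
    passive_curve: MaterialCurve | TissueMaterial | None = None,
) -> pd.DataFrame:
    """Angular change along the drying path on a uniform xi grid.

    Returns a DataFrame with columns ``xi, rh_percent, E_passive_MPa,
    eps_active, gamma_deg``.  ``rh_percent`` is the humidity at which the
    passive-modulus curve takes the path's modulus, clamped to the measured
    range (drying beyond the driest measurement keeps the label of the dry
    end).
    """
    from .materials import preset_curve  # local import to avoid cycle at module load

    if active_curve is None:
        active_curve = preset_curve("sclereid_regression")
    if passive_curve is None:
        passive_curve = preset_curve("sclerenchyma_sim")
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    curve = passive_curve.curve if isinstance(passive_curve, TissueMaterial) else passive_curve
    xis = np.linspace(0.0, 1.0, n_points)
    rows = []
    for xi in xis:
        state = _state_on_path(path, float(xi), active_curve, passive_curve)
        gamma = bend_scale(model, state).gamma_deg
        rows.append(
            dict(
                xi=float(xi),
                rh_percent=float(curve.rh_at_modulus(state.e_passive)),
                E_passive_MPa=state.e_passive,
                eps_active=state.eps_active,
                gamma_deg=gamma,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntervalPrediction:
    """Predicted response of the calibrated model over an rh interval."""

    rh_a: float
    rh_b: float
    gamma_deg: float  # angular change, state A -> state B
    modulus_change_mpa: float  # E_passive(rh_B) - E_passive(rh_A)
    state_a: TissueState
    state_b: TissueState


def predict_interval_angle(
    model: ScaleModel,
    path: DryingPath,
    rh_a: float,
    rh_b: float,
    *,
    active_curve: MaterialCurve | TissueMaterial | None = None,
    passive_curve: MaterialCurve | TissueMaterial | None = None,
) -> IntervalPrediction:
    """Angular change and passive-modulus change between two humidities.

    Each humidity maps to a drying coordinate through the passive-modulus
    curve and the path (``xi_from_rh``); contraction follows the path, the
    active modulus follows its own humidity curve.
    """
    from .materials import preset_curve

    if active_curve is None:
        active_curve = preset_curve("sclereid_regression")
    if passive_curve is None:
        passive_curve = preset_curve("sclerenchyma_sim")
    for rh in (rh_a, rh_b):
        if not (0.0 <= rh <= 100.0):
            raise DomainError(f"rh must be in [0, 100], got {rh}")

    def state(rh: float) -> TissueState:
        xi = xi_from_rh(path, passive_curve, rh)
        return TissueState(
            e_active=young_modulus(active_curve, rh),
            e_passive=young_modulus(passive_curve, rh),
            eps_active=path.active_strain(xi),
        )

    sa, sb = state(rh_a), state(rh_b)
    gamma = bend_scale(model, sb).gamma_deg - bend_scale(model, sa).gamma_deg
    return IntervalPrediction(
        rh_a=float(rh_a),
        rh_b=float(rh_b),
        gamma_deg=gamma,
        modulus_change_mpa=sb.e_passive - sa.e_passive,
        state_a=sa,
        state_b=sb,
    )
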