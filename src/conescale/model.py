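"""Model/Results facade over the bending-zone engine.

`ScaleActuationModel` bundles geometry, material curves and the drying path
into a single object, in the spirit of statsmodels model classes: build it
from data (an observed angle table) or from defaults, call :meth:`fit` to
obtain a :class:`ScaleActuationResults`, then predict, sweep, summarize or
plot off the results object.

Two fitting modes exist, matching how the underlying study identified its
parameters:

``method="calibrate"``
    Bracketed root-find of one parameter against a single target angle
    (e.g. the fully dry angular change).  Deterministic, noise-free.
``method="leastsq"``
    Least squares of predicted vs. observed angular changes over an rh
    grid -- the natural estimator for (synthetic or real) angle sweeps with
    measurement scatter; reports a standard error from the local Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import calibration as _cal
from .exceptions import CalibrationError, ConfigurationError, DomainError
from .geometry import ScaleModel, default_scale_model
from .materials import (
    DryingPath,
    MaterialCurve,
    TissueMaterial,
    preset_curve,
    xi_from_rh,
    young_modulus,
)
from .mechanics import BendResult, TissueState, bend_scale

__all__ = ["ScaleActuationModel", "ScaleActuationResults"]


class ScaleActuationModel:
    """Hygro-mechanical bending model of one seed scale.

    Parameters
    ----------
    observations : DataFrame, optional
        Angle observations with columns ``rh_percent`` and ``gamma_deg``
        (optionally ``scale_id``); angular change relative to the fully wet
        reference.  Required for ``fit(method="leastsq")``.
    scale : ScaleModel, optional
        Bending-zone geometry plus lever; defaults to the measured
        cross-sections with the package default zone length.
    drying : DryingPath, optional
        Contraction/stiffening coupling; defaults to 22 % maximal
        contraction between 70 and 1170 MPa passive modulus.
    passive_curve, active_curve : MaterialCurve or preset name
        Humidity curves of the two layers.
    """

    def __init__(
        self,
        observations: pd.DataFrame | None = None,
        *,
        scale: ScaleModel | None = None,
        drying: DryingPath | None = None,
        passive_curve: MaterialCurve | TissueMaterial | str = "sclerenchyma_sim",
        active_curve: MaterialCurve | TissueMaterial | str = "sclereid_regression",
    ) -> None:
        if observations is not None:
            missing = {"rh_percent", "gamma_deg"} - set(observations.columns)
            if missing:
                raise ConfigurationError(
                    f"observations lack columns: {sorted(missing)}"
                )
        self.observations = observations
        self.scale = scale if scale is not None else default_scale_model()
        self.drying = drying if drying is not None else DryingPath()
        self.passive_curve = (
            preset_curve(passive_curve) if isinstance(passive_curve, str) else passive_curve
        )
        self.active_curve = (
            preset_curve(active_curve) if isinstance(active_curve, str) else active_curve
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ScaleActuationModel":
        """Build from an angle-observation table (rh_percent, gamma_deg)."""
        return cls(observations=df, **kwargs)

    @classmethod
    def from_config(cls, config) -> "ScaleActuationModel":
        """Build from a :class:`conescale.config.RunConfig`."""
        from .config import build_model

        return build_model(config)

    # -- forward model -----------------------------------------------------

    def state_at_rh(self, rh: float, e_passive_dry: float | None = None) -> TissueState:
        """Tissue state at a humidity, given a dry-end passive modulus."""
        path = self.drying if e_passive_dry is None else self.drying.with_dry_modulus(e_passive_dry)
        xi = xi_from_rh(path, self.passive_curve, rh)
        return TissueState(
            e_active=young_modulus(self.active_curve, rh),
            e_passive=young_modulus(self.passive_curve, rh),
            eps_active=path.active_strain(xi),
        )

    def dry_state(self, e_passive_dry: float | None = None) -> TissueState:
        """Fully dry state: maximal contraction, dry moduli."""
        path = self.drying if e_passive_dry is None else self.drying.with_dry_modulus(e_passive_dry)
        return TissueState(
            e_active=young_modulus(self.active_curve, self.active_curve_rh_min()),
            e_passive=path.e_passive_dry,
            eps_active=-path.eps_max,
        )

    def active_curve_rh_min(self) -> float:
        curve = self.active_curve.curve if isinstance(self.active_curve, TissueMaterial) else self.active_curve
        return float(curve.rh_knots[0])

    def bend(self, state: TissueState) -> BendResult:
        return bend_scale(self.scale, state)

    def predict_gamma(self, rh, e_passive_dry: float | None = None,
                      scale: ScaleModel | None = None) -> np.ndarray:
        """Angular change vs. the wet reference at each humidity [deg]."""
        model = scale if scale is not None else self.scale
        path = self.drying if e_passive_dry is None else self.drying.with_dry_modulus(e_passive_dry)
        zone = model.zone
        s = zone.stations()
        sec = zone.section_at(s)
        rh = np.atleast_1d(np.asarray(rh, dtype=float))
        # broadcast stations x rh for one vectorized section solve
        from .mechanics import Layer, SectionState, section_response

        e_a = np.atleast_1d(young_modulus(self.active_curve, rh))
        e_p = np.atleast_1d(young_modulus(self.passive_curve, rh))
        eps = np.atleast_1d(path.active_strain(xi_from_rh(path, self.passive_curve, rh)))
        t_a = sec.t_active[:, None]
        t_p = sec.t_passive[:, None]
        w = sec.width[:, None]
        state = SectionState(layers=(
            Layer(t_a, w, e_a[None, :], eps[None, :], -t_a / 2.0),
            Layer(t_p, w, e_p[None, :], 0.0, +t_p / 2.0),
        ))
        kappa = section_response(state).kappa  # (stations, rh)
        if not model.active_below:
            kappa = -kappa
        theta_end = np.trapezoid(kappa, s, axis=0)
        return np.degrees(theta_end)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        method: Literal["calibrate", "leastsq"] = "calibrate",
        param: Literal["e_passive_dry", "contraction"] = "e_passive_dry",
        *,
        target_gamma_deg: float | None = None,
        target_gamma_sd_deg: float | None = None,
        bracket: tuple[float, float] | None = None,
        rh_interval: tuple[float, float] = (80.0, 30.0),
    ) -> "ScaleActuationResults":
        """Fit one parameter; returns a results object.

        ``method="calibrate"`` with ``param="e_passive_dry"`` root-finds the
        dry passive modulus against the dry-state target angle (default
        24.4 deg).  With ``param="contraction"`` it root-finds the
        contraction increment over ``rh_interval`` against the measured
        interval angle (default 12 deg).  ``method="leastsq"`` fits
        ``e_passive_dry`` to the model's observation table.
        """
        if method == "calibrate":
            if param == "e_passive_dry":
                target = 24.4 if target_gamma_deg is None else float(target_gamma_deg)
                br = _cal.DEFAULT_E_BRACKET if bracket is None else bracket
                res = _cal.fit_passive_modulus(
                    self.scale,
                    target_gamma_deg=target,
                    eps_active=-self.drying.eps_max,
                    e_active=young_modulus(self.active_curve, self.active_curve_rh_min()),
                    bracket=br,
                )
                bse = self._bse_from_target_sd(res, target_gamma_sd_deg)
                return ScaleActuationResults(
                    model=self, params=pd.Series({"e_passive_dry": res.fitted_value}),
                    bse=pd.Series({"e_passive_dry": bse}),
                    method="calibrate", calibration=res, nobs=1,
                    target_gamma_deg=target,
                )
            if param == "contraction":
                target = 12.0 if target_gamma_deg is None else float(target_gamma_deg)
                br = _cal.DEFAULT_EPS_BRACKET if bracket is None else bracket
                rh_a, rh_b = rh_interval
                e_p = (young_modulus(self.passive_curve, rh_a),
                       young_modulus(self.passive_curve, rh_b))
                e_a = (young_modulus(self.active_curve, rh_a),
                       young_modulus(self.active_curve, rh_b))
                eps_start = self.drying.active_strain(
                    xi_from_rh(self.drying, self.passive_curve, rh_a)
                )
                res = _cal.fit_contraction(
                    self.scale, target, ((e_p[0], e_a[0]), (e_p[1], e_a[1])),
                    eps_start=eps_start, bracket=br,
                )
                return ScaleActuationResults(
                    model=self, params=pd.Series({"contraction_increment": res.fitted_value}),
                    bse=pd.Series({"contraction_increment": np.nan}),
                    method="calibrate", calibration=res, nobs=1,
                    target_gamma_deg=target,
                )
            raise ConfigurationError(f"unknown param {param!r}")
        if method == "leastsq":
            return self._fit_leastsq(bracket=bracket)
        raise ConfigurationError(f"unknown fit method {method!r}")

    def _bse_from_target_sd(self, res: _cal.CalibrationResult,
                            sd: float | None) -> float:
        """Propagate a target-angle sd through the local sensitivity."""
        if sd is None:
            return np.nan
        e = res.fitted_value
        h = max(1e-4 * abs(e), 1e-6)
        g = lambda x: self.bend(
            TissueState(
                e_active=young_modulus(self.active_curve, self.active_curve_rh_min()),
                e_passive=x, eps_active=-self.drying.eps_max)
        ).gamma_deg
        slope = (g(e + h) - g(e - h)) / (2 * h)
        return abs(sd / slope) if slope != 0 else np.nan

    def _fit_leastsq(self, bracket: tuple[float, float] | None) -> "ScaleActuationResults":
        if self.observations is None:
            raise ConfigurationError("leastsq fit requires an observation table")
        br = (200.0, 5000.0) if bracket is None else (float(bracket[0]), float(bracket[1]))
        obs = self.observations
        rh = obs["rh_percent"].to_numpy(float)
        y = obs["gamma_deg"].to_numpy(float)
        rh_u, inv = np.unique(rh, return_inverse=True)

        def sse(e_dry: float) -> float:
            pred = self.predict_gamma(rh_u, e_passive_dry=e_dry)[inv]
            return float(np.sum((y - pred) ** 2))

        opt = minimize_scalar(sse, bounds=br, method="bounded",
                              options={"xatol": 1e-2})
        e_hat = float(opt.x)
        span = br[1] - br[0]
        at_bound = min(e_hat - br[0], br[1] - e_hat) < 1e-3 * span
        converged = bool(opt.success) and not at_bound
        pred = self.predict_gamma(rh_u, e_passive_dry=e_hat)[inv]
        resid = y - pred
        dof = max(len(y) - 1, 1)
        s2 = float(resid @ resid) / dof
        h = max(1e-4 * abs(e_hat), 1e-6)
        jac = (self.predict_gamma(rh_u, e_passive_dry=e_hat + h)[inv]
               - self.predict_gamma(rh_u, e_passive_dry=e_hat - h)[inv]) / (2 * h)
        jtj = float(jac @ jac)
        bse = np.sqrt(s2 / jtj) if jtj > 0 else np.nan
        return ScaleActuationResults(
            model=self,
            params=pd.Series({"e_passive_dry": e_hat}),
            bse=pd.Series({"e_passive_dry": bse}),
            method="leastsq",
            calibration=None,
            nobs=len(y),
            resid=resid,
            converged=converged,
        )


@dataclass
class ScaleActuationResults:
    """Fit results: estimates, uncertainty, diagnostics, postprocessing."""

    model: ScaleActuationModel
    params: pd.Series
    bse: pd.Series
    method: str
    calibration: _cal.CalibrationResult | None
    nobs: int
    resid: np.ndarray | None = None
    converged: bool = True
    target_gamma_deg: float | None = None

    def __post_init__(self) -> None:
        if self.calibration is not None:
            self.converged = self.calibration.converged

    # -- derived quantities ------------------------------------------------

    @property
    def fitted_path(self) -> DryingPath:
        if "e_passive_dry" in self.params.index:
            return self.model.drying.with_dry_modulus(self.params["e_passive_dry"])
        return self.model.drying

    def predict(self, rh) -> np.ndarray:
        """Angular change vs. the wet reference at each humidity [deg]."""
        e = self.params.get("e_passive_dry", None)
        return self.model.predict_gamma(rh, e_passive_dry=e)

    def drying_sweep(self, n_points: int = 51) -> pd.DataFrame:
        return _cal.drying_sweep(
            self.model.scale, self.fitted_path, n_points,
            active_curve=self.model.active_curve,
            passive_curve=self.model.passive_curve,
        )

    def interval_angle(self, rh_a: float = 80.0, rh_b: float = 30.0) -> _cal.IntervalPrediction:
        return _cal.predict_interval_angle(
            self.model.scale, self.fitted_path, rh_a, rh_b,
            active_curve=self.model.active_curve,
            passive_curve=self.model.passive_curve,
        )

    def plot_sweep(self, ax=None, n_points: int = 101):
        """Plot angular change vs. drying coordinate (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.drying_sweep(n_points)
        ax.plot(tab["xi"], tab["gamma_deg"], lw=2)
        ax.set_xlabel("drying coordinate $\\xi$ (0 = wet, 1 = dry)")
        ax.set_ylabel("angular change $\\gamma$ [deg]")
        return ax

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Scale actuation model fit",
            "=" * 60,
            f"method:              {self.method}",
            f"n observations:      {self.nobs}",
            f"converged:           {self.converged}",
        ]
        if self.target_gamma_deg is not None:
            lines.append(f"target angle [deg]:  {self.target_gamma_deg:g}")
        if self.calibration is not None:
            c = self.calibration
            lines += [
                f"residual [deg]:      {c.residual_deg:.3g}",
                f"iterations:          {c.iterations}",
                f"bracket:             [{c.bracket[0]:g}, {c.bracket[1]:g}]",
            ]
        if self.resid is not None:
            rmse = float(np.sqrt(np.mean(self.resid**2)))
            lines.append(f"residual RMSE [deg]: {rmse:.4g}")
        lines.append("-" * 60)
        lines.append(f"{'parameter':<24}{'estimate':>14}{'std err':>14}")
        for name in self.params.index:
            se = self.bse.get(name, np.nan)
            se_s = f"{se:.6g}" if np.isfinite(se) else "--"
            lines.append(f"{name:<24}{self.params[name]:>14.6g}{se_s:>14}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def __repr__(self) -> str:
        pars = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return f"<ScaleActuationResults {self.method}: {pars}>"
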