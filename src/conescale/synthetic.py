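"""Synthetic study observations and parameter recovery.

No raw measurements ship with the underlying study, so validation of the
inverse machinery rests on synthetic observations that carry the *reported*
scatter structure:

* tip-angle sweeps over 30--80 % rh in 10 % steps, with Gaussian angular
  noise (the measured between-scale spread is 4.2 deg) and a per-scale
  lognormal size factor on the bending-zone length standing in for the wide
  range of scale sizes;
* indentation-modulus tables with 64 sampling locations per (tissue, rh)
  and large multiplicative (lognormal) scatter.

`recover_parameters` closes the loop: it refits the dry-end passive modulus
per synthetic scale by least squares over the rh grid and aggregates the
per-scale estimates into a study-level estimate with bias and RMSE.
Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .geometry import ScaleModel, default_scale_model
from .materials import DryingPath, MaterialCurve, TissueMaterial, young_modulus
from .model import ScaleActuationModel

__all__ = [
    "SyntheticStudy",
    "StudyTruth",
    "RecoveryReport",
    "generate_angle_observations",
    "generate_modulus_observations",
    "generate_study",
    "recover_parameters",
    "recovery_experiment",
    "RH_GRID_DEFAULT",
]

#: Measurement grid of the humidity sweep: 30 -> 80 % rh in 10 % steps.
RH_GRID_DEFAULT = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

#: Between-scale angular spread reported for uncoated scales [deg].
NOISE_SD_DEFAULT = 4.2

#: Coefficient of variation of the per-scale size factor on the zone length.
SIZE_CV_DEFAULT = 0.15

#: Indentation locations per (tissue, rh) sample.
N_LOCATIONS_DEFAULT = 64


@dataclass(frozen=True)
class StudyTruth:
    """Ground-truth parameters behind a synthetic study."""

    e_passive_dry: float = 1170.0  # MPa
    eps_max: float = 0.22
    length_mm: float | None = None  # None -> the geometry default


@dataclass(frozen=True)
class SyntheticStudy:
    """A reproducible synthetic data set (seed + truth + tables)."""

    seed: int
    truth: StudyTruth
    angle_obs: pd.DataFrame
    modulus_obs: pd.DataFrame | None = None
    noise_sd_deg: float = NOISE_SD_DEFAULT
    size_cv: float = SIZE_CV_DEFAULT
    rh_grid: tuple[float, ...] = RH_GRID_DEFAULT


def _size_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Lognormal size factors with median 1 (mu=0, sigma from the cv)."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=n)


def generate_angle_observations(
    truth: StudyTruth = StudyTruth(),
    rh_grid=RH_GRID_DEFAULT,
    n_scales: int = 10,
    noise_sd_deg: float = NOISE_SD_DEFAULT,
    seed: int = 0,
    *,
    size_cv: float = SIZE_CV_DEFAULT,
    base_model: ScaleActuationModel | None = None,
) -> pd.DataFrame:
    """Synthetic tip-angle observations over a humidity sweep.

    For each of ``n_scales`` scales, the forward model (with the scale's own
    lognormal size factor on the bending-zone length) is evaluated on the rh
    grid and Gaussian noise of sd ``noise_sd_deg`` is added.  Returns a tidy
    table ``scale_id, rh_percent, gamma_deg, gamma_true_deg, length_factor``.
    Deterministic per ``seed``.
    """
    rh_grid = tuple(float(r) for r in rh_grid)
    if len(rh_grid) == 0:
        raise ConfigurationError("empty rh grid")
    if n_scales < 1:
        raise ConfigurationError("n_scales must be >= 1")
    if noise_sd_deg < 0:
        raise ConfigurationError("noise_sd_deg must be >= 0")
    model = base_model if base_model is not None else ScaleActuationModel(
        drying=DryingPath(eps_max=truth.eps_max, e_passive_dry=truth.e_passive_dry)
    )
    base_scale = model.scale
    if truth.length_mm is not None:
        base_scale = base_scale.with_length(truth.length_mm)
    rng = np.random.default_rng(seed)
    factors = _size_factors(rng, n_scales, size_cv)
    rows = []
    rh_arr = np.asarray(rh_grid)
    for i, fac in enumerate(factors):
        scale_i = base_scale.with_length(base_scale.zone.length_mm * fac)
        gamma_true = model.predict_gamma(
            rh_arr, e_passive_dry=truth.e_passive_dry, scale=scale_i
        )
        noise = rng.normal(0.0, noise_sd_deg, size=len(rh_arr))
        for rh, gt, g in zip(rh_arr, gamma_true, gamma_true + noise):
            rows.append(dict(scale_id=i, rh_percent=float(rh),
                             gamma_deg=float(g), gamma_true_deg=float(gt),
                             length_factor=float(fac)))
    return pd.DataFrame(rows)


def generate_modulus_observations(
    curves: dict[str, MaterialCurve] | None = None,
    rh_values=RH_GRID_DEFAULT,
    n_locations: int = N_LOCATIONS_DEFAULT,
    cv: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic indentation-modulus tables with per-location scatter.

    Lognormal multiplicative noise (mean 1, coefficient of variation ``cv``)
    around the curve value guarantees positive moduli.  Returns a tidy table
    ``tissue, rh_percent, location_id, E_obs_MPa, E_true_MPa``.
    """
    from .materials import preset_curve

    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    if curves is None:
        curves = {n: preset_curve(n) for n in ("sclerenchyma_afm", "sclereid_afm",
                                               "brown_tissue")}
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sigma**2  # mean-1 multiplicative noise
    rows = []
    for tissue, curve in curves.items():
        for rh in rh_values:
            e_true = float(young_modulus(curve, rh))
            mult = (rng.lognormal(mu, sigma, size=n_locations)
                    if cv > 0 else np.ones(n_locations))
            for loc, m in enumerate(mult):
                rows.append(dict(tissue=tissue, rh_percent=float(rh),
                                 location_id=loc, E_obs_MPa=e_true * m,
                                 E_true_MPa=e_true))
    return pd.DataFrame(rows)


def generate_study(
    seed: int = 0,
    truth: StudyTruth = StudyTruth(),
    *,
    rh_grid=RH_GRID_DEFAULT,
    n_scales: int = 10,
    noise_sd_deg: float = NOISE_SD_DEFAULT,
    size_cv: float = SIZE_CV_DEFAULT,
    with_moduli: bool = False,
    base_model: ScaleActuationModel | None = None,
) -> SyntheticStudy:
    """One full synthetic study (angles, optionally modulus tables)."""
    angle_obs = generate_angle_observations(
        truth, rh_grid, n_scales, noise_sd_deg, seed,
        size_cv=size_cv, base_model=base_model,
    )
    modulus_obs = (
        generate_modulus_observations(rh_values=rh_grid, seed=seed + 1)
        if with_moduli else None
    )
    return SyntheticStudy(
        seed=seed, truth=truth, angle_obs=angle_obs, modulus_obs=modulus_obs,
        noise_sd_deg=noise_sd_deg, size_cv=size_cv,
        rh_grid=tuple(float(r) for r in rh_grid),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of refitting the dry passive modulus from one study."""

    per_scale: pd.DataFrame  # scale_id, e_passive_dry_hat, converged
    estimate: float  # study-level estimate (mean of converged fits)
    truth: float
    bias: float
    relative_bias: float
    rmse_across_replicates: float
    n_converged: int
    n_failed: int

    def __str__(self) -> str:
        return (
            f"e_passive_dry: estimate={self.estimate:.1f} MPa "
            f"(truth {self.truth:.1f}), relative bias "
            f"{100 * self.relative_bias:.2f} %, replicate RMSE "
            f"{self.rmse_across_replicates:.1f} MPa, "
            f"{self.n_converged} converged / {self.n_failed} failed"
        )


def recover_parameters(
    study: SyntheticStudy,
    *,
    base_model: ScaleActuationModel | None = None,
    bracket: tuple[float, float] = (200.0, 5000.0),
) -> RecoveryReport:
    """Refit ``e_passive_dry`` per synthetic scale; aggregate across scales.

    Each scale (replicate) is fit independently by least squares of
    predicted vs. observed angles over its rh grid.  Fits that end on the
    bracket boundary are flagged non-convergent and excluded from the
    aggregates; the study-level estimate is the mean of converged fits.
    """
    model = base_model if base_model is not None else ScaleActuationModel(
        drying=DryingPath(eps_max=study.truth.eps_max)
    )
    recs = []
    for sid, grp in study.angle_obs.groupby("scale_id", sort=True):
        m = ScaleActuationModel(
            observations=grp,
            scale=model.scale,
            drying=model.drying,
            passive_curve=model.passive_curve,
            active_curve=model.active_curve,
        )
        res = m.fit(method="leastsq", bracket=bracket)
        recs.append(dict(scale_id=sid,
                         e_passive_dry_hat=float(res.params["e_passive_dry"]),
                         converged=bool(res.converged)))
    per_scale = pd.DataFrame(recs)
    ok = per_scale[per_scale["converged"]]
    truth = study.truth.e_passive_dry
    if len(ok):
        est = float(ok["e_passive_dry_hat"].mean())
        rmse = float(np.sqrt(np.mean((ok["e_passive_dry_hat"] - truth) ** 2)))
    else:
        est = np.nan
        rmse = np.nan
    bias = est - truth
    return RecoveryReport(
        per_scale=per_scale,
        estimate=est,
        truth=truth,
        bias=bias,
        relative_bias=bias / truth,
        rmse_across_replicates=rmse,
        n_converged=int(len(ok)),
        n_failed=int(len(per_scale) - len(ok)),
    )


def recovery_experiment(
    n_seeds: int = 200,
    n_scales_list=(5, 20, 80),
    noise_sd_deg: float = 1.0,
    truth: StudyTruth = StudyTruth(),
    *,
    size_cv: float = SIZE_CV_DEFAULT,
    seed: int = 0,
    rh_grid=RH_GRID_DEFAULT,
) -> pd.DataFrame:
    """Monte-Carlo recovery: study-level estimates across seeds and sizes.

    Returns one row per (n_scales, replicate seed) with the study-level
    estimate; summarize with e.g.
    ``df.groupby("n_scales")["estimate"].agg(["median", "std"])``.
    Seeds for the individual studies are derived deterministically from
    ``seed``.
    """
    base_model = ScaleActuationModel(drying=DryingPath(eps_max=truth.eps_max))
    rows = []
    for n_scales in n_scales_list:
        for rep in range(n_seeds):
            study_seed = (seed * 1_000_003 + n_scales * 1009 + rep) % (2**31 - 1)
            study = generate_study(
                seed=study_seed, truth=truth, rh_grid=rh_grid,
                n_scales=n_scales, noise_sd_deg=noise_sd_deg,
                size_cv=size_cv, base_model=base_model,
            )
            rep_report = recover_parameters(study, base_model=base_model)
            rows.append(dict(
                n_scales=n_scales, replicate=rep, seed=study_seed,
                estimate=rep_report.estimate,
                relative_bias=rep_report.relative_bias,
                n_failed=rep_report.n_failed,
            ))
    return pd.DataFrame(rows)
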