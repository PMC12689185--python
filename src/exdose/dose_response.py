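"""Bayesian dose-response meta-regression of HbA1c change on weekly dose.

Arm-level mean changes are modelled with a normal likelihood and identity
link,

    change_i ~ N(alpha_study(i) + f(dose_i) + g(bmi) + h(dose_i, bmi),
                 se_i^2 + sigma^2),

where f is a restricted (natural) cubic spline of the weekly dose in
METs·min/week with four knots at the 5th/35th/65th/95th percentiles of the
nonzero doses, g is a linear baseline-BMI term, h an optional dose-spline ×
BMI-linear interaction, study random intercepts absorb trial effects and
sigma is a residual heterogeneity SD.  Because every spline column vanishes
at dose 0 (knots are positive, the linear term is the dose itself), the
fitted mean change from baseline (MCFB) relative to no exercise is anchored
to exactly 0 at dose 0.

From the fitted curve the module derives the optimal dose (grid argmin of
the posterior mean), the minimal statistically effective dose (smallest grid
dose whose 95% interval excludes 0) and the minimal clinically effective
dose (smallest grid dose whose entire 95% interval lies beyond the MCID of
−0.2% HbA1c).  A companion model sweeps intensity (METs) at a fixed weekly
duration of 150 minutes, and a per-modality variant adds modality-specific
linear dose adjustments on top of the shared spline shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import HierRegressionGibbs
from .dose import weekly_dose
from .effects import arm_change

__all__ = [
    "SplineSpec",
    "McmcSpec",
    "DoseObservation",
    "DoseResponseCurve",
    "DoseThresholds",
    "DoseResponsePosterior",
    "DEFAULT_GRID",
    "BMI_REPRESENTATIVE",
    "MCID",
    "rcs_basis",
    "default_knots",
    "spline_basis",
    "observations_from_arms",
    "fit_dose_response",
    "predict_curve",
    "find_thresholds",
    "fit_intensity_model",
    "predict_intensity",
    "per_modality_curves",
]

#: Dose grid for predictions, METs·min/week.
DEFAULT_GRID = np.arange(0, 1501, 50)
#: Representative BMI per category for stratified predictions (kg/m²).
BMI_REPRESENTATIVE = {"normal": 22.0, "overweight": 26.0, "obesity": 29.5}
#: Minimal clinically important difference for HbA1c change (%).
MCID = -0.2


@dataclass(frozen=True)
class SplineSpec:
    n_knots: int = 4
    knots: tuple | None = None  # explicit knot locations override placement
    quantiles: tuple = (0.05, 0.35, 0.65, 0.95)


@dataclass(frozen=True)
class McmcSpec:
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class DoseObservation:
    """One arm's change summary with its weekly dose and study covariates."""

    study_id: str
    modality: str
    dose: float  # METs·min/week; 0 for usual care
    bmi: float
    change_mean: float
    change_se: float
    n: int
    weekly_minutes: float | None = None
    mets: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.change_se <= 0:
            raise ValueError("change SE must be positive")


@dataclass
class DoseResponseCurve:
    """Posterior MCFB summaries on the dose grid for one stratum."""

    frame: pd.DataFrame  # dose, mean, cri_low, cri_high, extrapolated
    stratum: str = "overall"

    @property
    def dose(self) -> np.ndarray:
        return self.frame["dose"].to_numpy()

    @property
    def mean(self) -> np.ndarray:
        return self.frame["mean"].to_numpy()


@dataclass(frozen=True)
class DoseThresholds:
    optimal: float
    minimal_statistical: float | None
    minimal_clinical: float | None
    mcid: float = MCID


@dataclass
class DoseResponsePosterior:
    knots: np.ndarray
    bmi_center: float
    n_spline: int
    interaction: bool
    beta: np.ndarray  # (chains, draws, q) fixed-effect draws
    sigma: np.ndarray
    sigma_alpha: np.ndarray
    max_dose: float
    colnames: list[str] = field(default_factory=list)
    modality_slopes: dict = field(default_factory=dict)  # name -> column index

    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])


# -- spline basis ----------------------------------------------------------


def default_knots(doses: np.ndarray, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Knots at quantiles of the observed nonzero doses."""
    if spec.knots is not None:
        return np.asarray(spec.knots, float)
    pos = np.asarray(doses, float)
    pos = pos[pos > 0]
    qs = spec.quantiles[: spec.n_knots]
    knots = np.quantile(pos, qs)
    if len(np.unique(knots)) != spec.n_knots:
        raise ValueError("degenerate knot placement (too few distinct doses)")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    Columns: x itself plus k−2 nonlinear terms, each a combination of
    truncated cubes scaled by (t_k − t_1)² so coefficients stay on a common
    scale.  The function is linear beyond the boundary knots and every
    column is exactly 0 at x = 0 (knots are positive).
    """
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    k = len(t)
    if k < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def spline_basis(doses: np.ndarray, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Basis matrix for observed doses with automatic knot placement."""
    doses = np.asarray(doses, float)
    if len(np.unique(doses)) < max(spec.n_knots + 1, 5):
        raise ValueError("need at least 5 distinct dose values for the spline")
    return rcs_basis(doses, default_knots(doses, spec))


# -- observation assembly --------------------------------------------------


def observations_from_arms(arms, metas, r: float = 0.5) -> list[DoseObservation]:
    """Build dose observations from arm records: UC arms anchor dose 0."""
    meta_by_id = {m.study_id: m for m in metas}
    out = []
    for arm in arms:
        mean, sd = arm_change(arm, r)
        meta = meta_by_id.get(arm.study_id)
        bmi = meta.baseline_bmi if meta is not None else np.nan
        if arm.modality == "UC" or arm.prescription is None:
            dose, minutes, mets = 0.0, 0.0, 0.0
        else:
            dose = weekly_dose(arm.prescription)
            minutes = sum(
                ph.minutes for ph in arm.prescription.phases
            ) * arm.prescription.sessions_per_week
            mets = dose / minutes if minutes > 0 else 0.0
        out.append(
            DoseObservation(
                study_id=arm.study_id,
                modality=arm.modality,
                dose=dose,
                bmi=float(bmi),
                change_mean=mean,
                change_se=sd / np.sqrt(arm.n),
                n=arm.n,
                weekly_minutes=minutes,
                mets=mets,
            )
        )
    return out


# -- model fitting ---------------------------------------------------------


def _study_index(obs) -> tuple[np.ndarray, list[str]]:
    studies = sorted({o.study_id for o in obs})
    idx = {s: i for i, s in enumerate(studies)}
    return np.array([idx[o.study_id] for o in obs]), studies


def fit_dose_response(
    observations: list[DoseObservation],
    spline: SplineSpec = SplineSpec(),
    mcmc: McmcSpec = McmcSpec(),
    bmi_center: float | None = None,
    interaction: bool = True,
) -> DoseResponsePosterior:
    """Fit the BMI-adjusted spline dose-response model."""
    obs = list(observations)
    doses = np.array([o.dose for o in obs])
    if not np.any(doses == 0):
        warnings.warn(
            "no zero-dose (usual care) arms: curve is not anchored at dose 0",
            stacklevel=2,
        )
    knots = default_knots(doses, spline)
    B = rcs_basis(doses, knots)
    bmis = np.array([o.bmi for o in obs])
    if bmi_center is None:
        bmi_center = float(np.nanmean(bmis))
    bmi_c = np.nan_to_num(bmis - bmi_center)
    cols = [B, bmi_c[:, None]]
    names = [f"spline_{j}" for j in range(B.shape[1])] + ["bmi"]
    if interaction:
        cols.append(B * bmi_c[:, None])
        names += [f"spline_{j}:bmi" for j in range(B.shape[1])]
    Z = np.hstack(cols)
    y = np.array([o.change_mean for o in obs])
    se2 = np.array([o.change_se**2 for o in obs])
    s_idx, _ = _study_index(obs)
    sampler = HierRegressionGibbs(
        y, se2, Z, s_idx, prior_sd=10.0, sigma_prior=0.3, alpha_prior=0.5
    )
    res = sampler.run(
        chains=mcmc.chains, draws=mcmc.draws, warmup=mcmc.warmup, seed=mcmc.seed
    )
    return DoseResponsePosterior(
        knots=knots,
        bmi_center=bmi_center,
        n_spline=B.shape[1],
        interaction=interaction,
        beta=res["beta"],
        sigma=res["sigma"],
        sigma_alpha=res["sigma_alpha"],
        max_dose=float(doses.max()),
        colnames=names,
    )


def _curve_draws(
    post: DoseResponsePosterior, grid: np.ndarray, bmi: float | None
) -> np.ndarray:
    Bg = rcs_basis(grid, post.knots)
    beta = post.beta_flat()
    q = post.n_spline
    contrib = Bg @ beta[:, :q].T
    if post.interaction and bmi is not None:
        inter = beta[:, q + 1 : q + 1 + q]
        contrib = contrib + (bmi - post.bmi_center) * (Bg @ inter.T)
    return contrib.T  # (ndraws, G)


def predict_curve(
    post: DoseResponsePosterior,
    grid: np.ndarray = DEFAULT_GRID,
    bmi: float | str | None = None,
    stratum: str | None = None,
) -> DoseResponseCurve:
    """Posterior MCFB curve relative to dose 0 at a given BMI (or category).

    Doses beyond the maximum observed dose are flagged as extrapolated, not
    refused.
    """
    if isinstance(bmi, str):
        stratum = stratum or bmi
        bmi = BMI_REPRESENTATIVE[bmi]
    grid = np.asarray(grid, float)
    draws = _curve_draws(post, grid, bmi)
    frame = pd.DataFrame(
        {
            "dose": grid,
            "mean": draws.mean(axis=0),
            "cri_low": np.quantile(draws, 0.025, axis=0),
            "cri_high": np.quantile(draws, 0.975, axis=0),
            "extrapolated": grid > post.max_dose,
        }
    )
    return DoseResponseCurve(frame=frame, stratum=stratum or "overall")


def find_thresholds(curve: DoseResponseCurve, mcid: float = MCID) -> DoseThresholds:
    """Optimal, minimal-statistical and minimal-clinical doses from a curve."""
    f = curve.frame
    dose = f["dose"].to_numpy()
    mean = f["mean"].to_numpy()
    hi = f["cri_high"].to_numpy()
    optimal = float(dose[int(np.argmin(mean))])  # ties -> lowest dose
    nz = dose > 0
    stat = dose[nz & (hi < 0)]
    clin = dose[nz & (hi <= mcid)]
    return DoseThresholds(
        optimal=optimal,
        minimal_statistical=float(stat[0]) if stat.size else None,
        minimal_clinical=float(clin[0]) if clin.size else None,
        mcid=mcid,
    )


# -- intensity model -------------------------------------------------------


def fit_intensity_model(
    observations: list[DoseObservation],
    spline: SplineSpec = SplineSpec(),
    mcmc: McmcSpec = McmcSpec(),
) -> DoseResponsePosterior:
    """Additive spline model in weekly duration (minutes) and intensity (METs).

    Requires intensity for at least 80% of exercise arms; predictions sweep
    intensity at a fixed weekly duration.
    """
    obs = list(observations)
    active = [o for o in obs if o.dose > 0]
    missing = sum(1 for o in active if not o.mets)
    if active and missing > 0.2 * len(active):
        raise ValueError("intensity missing for more than 20% of exercise arms")
    minutes = np.array([o.weekly_minutes or 0.0 for o in obs])
    mets = np.array([o.mets or 0.0 for o in obs])
    try:
        kd = default_knots(minutes, spline)
        Bd = rcs_basis(minutes, kd)
    except ValueError:
        # near-constant durations (e.g. a fixed-duration design): linear term
        kd = None
        Bd = minutes[:, None] / 100.0
    ki = default_knots(mets, spline)
    Bi = rcs_basis(mets, ki)
    Z = np.hstack([Bd, Bi])
    y = np.array([o.change_mean for o in obs])
    se2 = np.array([o.change_se**2 for o in obs])
    s_idx, _ = _study_index(obs)
    sampler = HierRegressionGibbs(
        y, se2, Z, s_idx, prior_sd=10.0, sigma_prior=0.3, alpha_prior=0.5
    )
    res = sampler.run(
        chains=mcmc.chains, draws=mcmc.draws, warmup=mcmc.warmup, seed=mcmc.seed
    )
    post = DoseResponsePosterior(
        knots=ki,
        bmi_center=0.0,
        n_spline=Bi.shape[1],
        interaction=False,
        beta=res["beta"],
        sigma=res["sigma"],
        sigma_alpha=res["sigma_alpha"],
        max_dose=float(mets.max()),
        colnames=[f"dur_{j}" for j in range(Bd.shape[1])]
        + [f"int_{j}" for j in range(Bi.shape[1])],
    )
    post.modality_slopes = {"duration_knots": kd, "n_dur": Bd.shape[1]}
    return post


def predict_intensity(
    post: DoseResponsePosterior,
    duration: float = 150.0,
    grid: np.ndarray | None = None,
    mcid: float = MCID,
) -> dict:
    """Intensity sweep at fixed weekly duration, with threshold estimates.

    Returns the curve frame, the smallest intensity whose 95% interval
    excludes 0, and the smallest whose posterior mean reaches the MCID.
    """
    if grid is None:
        grid = np.round(np.arange(1.6, 12.01, 0.1), 2)
    kd = post.modality_slopes["duration_knots"]
    nd = post.modality_slopes["n_dur"]
    beta = post.beta_flat()
    if kd is None:
        bd = np.array([duration / 100.0])
    else:
        bd = rcs_basis(np.array([duration]), kd)[0]
    dur_term = beta[:, :nd] @ bd
    Bi = rcs_basis(grid, post.knots)
    draws = dur_term[:, None] + beta[:, nd:] @ Bi.T
    mean = draws.mean(axis=0)
    hi = np.quantile(draws, 0.975, axis=0)
    lo = np.quantile(draws, 0.025, axis=0)
    frame = pd.DataFrame(
        {"mets": grid, "mean": mean, "cri_low": lo, "cri_high": hi}
    )
    sig = grid[hi < 0]
    clin = grid[mean <= mcid]
    bands = {}
    for band, m in (("light", 2.25), ("moderate", 4.5), ("vigorous", 7.0)):
        b = rcs_basis(np.array([m]), post.knots)[0]
        d = dur_term + beta[:, nd:] @ b
        bands[band] = {
            "mets": m,
            "mean": float(d.mean()),
            "cri_low": float(np.quantile(d, 0.025)),
            "cri_high": float(np.quantile(d, 0.975)),
        }
    return {
        "curve": frame,
        "duration": duration,
        "min_significant_mets": float(sig[0]) if sig.size else None,
        "min_clinical_mets": float(clin[0]) if clin.size else None,
        "bands": bands,
    }


# -- per-modality curves ---------------------------------------------------


def per_modality_curves(
    observations: list[DoseObservation],
    spline: SplineSpec = SplineSpec(),
    mcmc: McmcSpec = McmcSpec(),
    grid: np.ndarray = DEFAULT_GRID,
    mcid: float = MCID,
) -> dict:
    """Dose-response curves and thresholds per exercise modality.

    All modalities share the global spline shape; each (except the
    best-represented, which serves as the base) adds a modality-specific
    linear dose adjustment.  Modalities with fewer than 2 trials are
    excluded with a warning.
    """
    obs = list(observations)
    trials_per_mod: dict[str, set] = {}
    for o in obs:
        if o.dose > 0:
            trials_per_mod.setdefault(o.modality, set()).add(o.study_id)
    included = {m for m, s in trials_per_mod.items() if len(s) >= 2}
    for m in sorted(set(trials_per_mod) - included):
        warnings.warn(f"modality {m} has < 2 trials; excluded", stacklevel=2)
    obs = [o for o in obs if o.dose == 0 or o.modality in included]
    doses = np.array([o.dose for o in obs])
    knots = default_knots(doses, spline)
    B = rcs_basis(doses, knots)
    base = max(included, key=lambda m: len(trials_per_mod[m]))
    others = sorted(included - {base})
    adj = np.column_stack(
        [
            (doses / 1000.0) * np.array([o.modality == m for o in obs], float)
            for m in others
        ]
    ) if others else np.empty((len(obs), 0))
    Z = np.hstack([B, adj])
    y = np.array([o.change_mean for o in obs])
    se2 = np.array([o.change_se**2 for o in obs])
    s_idx, _ = _study_index(obs)
    sampler = HierRegressionGibbs(
        y, se2, Z, s_idx, prior_sd=10.0, sigma_prior=0.3, alpha_prior=0.5
    )
    res = sampler.run(
        chains=mcmc.chains, draws=mcmc.draws, warmup=mcmc.warmup, seed=mcmc.seed
    )
    beta = res["beta"].reshape(-1, Z.shape[1])
    q = B.shape[1]
    Bg = rcs_basis(np.asarray(grid, float), knots)
    shared = beta[:, :q] @ Bg.T  # (ndraws, G)
    out = {}
    max_dose = float(doses.max())
    for m in sorted(included):
        draws = shared.copy()
        if m != base:
            j = q + others.index(m)
            draws = draws + beta[:, j][:, None] * (np.asarray(grid) / 1000.0)
        frame = pd.DataFrame(
            {
                "dose": grid,
                "mean": draws.mean(axis=0),
                "cri_low": np.quantile(draws, 0.025, axis=0),
                "cri_high": np.quantile(draws, 0.975, axis=0),
                "extrapolated": np.asarray(grid) > max_dose,
            }
        )
        curve = DoseResponseCurve(frame=frame, stratum=m)
        out[m] = {"curve": curve, "thresholds": find_thresholds(curve, mcid)}
    return out
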