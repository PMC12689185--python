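"""Synthetic study-level datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
six-node treatment network (usual care plus five exercise modalities) of
mostly usual-care-anchored two- and three-arm trials, arm-level normal
change outcomes, contrast-level between-study heterogeneity tau with the
multi-arm tau²/2 correlation, a J-shaped dose-response truth with BMI
effect modification, prescriptions whose computed weekly dose reproduces
the drawn dose exactly, and binomial adherence with per-modality completion
odds.  Every generated quantity with downstream relevance is recorded in a
:class:`TruthLedger` so that recovery tests compare estimates to the
generator's truth, never to published values.

The dose-response truth is an Emax (Hill) family with a mild quadratic
upturn beyond the plateau — deliberately not a spline, so spline-fit
recovery tests are not circular:

    E(d, b) = (E_max + k_bmi (b − b_ref)) d^h / (ED50^h + d^h)
              + upturn ((min(d, cap) − plateau)/100)²  for d > plateau,

anchored at E(0, b) = 0 for every BMI b; the post-plateau harm saturates at
the cap dose so extreme doses show a loss of benefit rather than runaway
harm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import StudyArm, StudyMeta
from .dose import Component, Phase, Prescription, weekly_dose
from .effects import Contrast

__all__ = [
    "GeneratorConfig",
    "TruthLedger",
    "true_curve",
    "generate_network",
    "generate_loop_contrasts",
]

_COUNTRIES = (
    "China", "India", "Korea", "Iran", "Germany", "Sweden", "Spain",
    "USA", "Brazil", "Egypt", "Canada", "Finland",
)

#: (METs low, METs high) per modality for prescription drawing.
_MET_RANGES = {
    "AT": (4.0, 7.0),
    "RT": (3.0, 6.0),
    "HIIT": (7.0, 11.0),
    "MBT": (3.0, 6.0),
    "CT": (3.0, 6.5),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic network."""

    n_trials: int = 39
    modality_mix: dict = field(
        default_factory=lambda: {
            "AT": 0.34, "RT": 0.16, "CT": 0.16, "HIIT": 0.18, "MBT": 0.16,
        }
    )
    p_three_arm: float = 0.2
    p_uc_anchor: float = 0.85
    #: basic parameters, % HbA1c versus usual care
    d_k: dict = field(
        default_factory=lambda: {
            "HIIT": -0.5, "CT": -0.34, "AT": -0.28, "RT": -0.28, "MBT": -0.21,
        }
    )
    tau: float = 0.126  # between-study SD (sqrt of 0.016)
    #: "modality" (fixed d_k), "dose" (pure curve), or "combined"
    effect_model: str = "combined"
    # dose-response truth (Emax family with post-plateau upturn)
    emax: float = -0.35
    ed50: float = 500.0
    hill: float = 4.0
    plateau: float = 850.0
    upturn: float = 0.05
    upturn_cap_dose: float = 1150.0  # harm saturates beyond this dose
    bmi_interaction: float = -0.01  # % HbA1c per kg/m² scaling of the curve
    bmi_ref: float = 26.85
    # populations
    bmi_mean: float = 26.85
    bmi_sd: float = 2.5
    bmi_range: tuple = (20.0, 34.0)
    age_mean: float = 55.82
    age_sd: float = 6.0
    pct_male_mean: float = 45.9
    baseline_hba1c_mean: float = 6.0
    baseline_hba1c_sd: float = 0.15
    # arm sizes and outcome noise
    assigned_median: float = 42.0
    assigned_log_sd: float = 0.4
    n_range: tuple = (10, 200)
    outcome_sd: float = 0.45
    outcome_sd_jitter: float = 0.05
    drift_mean: float = -0.03  # usual-care mean change (regression to mean)
    drift_sd: float = 0.05
    p_report_change: float = 0.7
    # adherence
    adherence_rate: float = 0.85
    adherence_or: dict = field(
        default_factory=lambda: {
            "AT": 1.6, "RT": 2.2, "CT": 2.5, "HIIT": 0.9, "MBT": 1.1,
        }
    )
    # risk of bias proportions (low, some_concerns, high)
    rob_probs: tuple = (0.18, 0.69, 0.13)
    grid_step: float = 50.0
    grid_max: float = 1500.0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if abs(sum(self.modality_mix.values()) - 1.0) > 1e-9:
            raise ValueError("modality mix proportions must sum to 1")
        if self.tau < 0 or self.outcome_sd <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass
class TruthLedger:
    """Ground truth recorded at generation time."""

    seed: int
    d_k: dict
    tau: float
    effect_model: str
    arms: pd.DataFrame  # study_id, modality, dose, bmi, true_effect
    curve_grid: np.ndarray
    curve_values: dict  # stratum -> true curve values on the grid
    true_optimal: float
    true_minimal_clinical: dict  # stratum -> dose or None (point truth)
    n_trials: int
    n_arms: int
    n_participants: int
    edge_counts: dict

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "d_k": self.d_k,
            "tau": self.tau,
            "effect_model": self.effect_model,
            "true_optimal": self.true_optimal,
            "true_minimal_clinical": self.true_minimal_clinical,
            "n_trials": self.n_trials,
            "n_arms": self.n_arms,
            "n_participants": self.n_participants,
            "edge_counts": {" vs ".join(sorted(k)): v for k, v in self.edge_counts.items()},
            "curve_grid": list(map(float, self.curve_grid)),
            "curve_values": {k: list(map(float, v)) for k, v in self.curve_values.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def true_curve(dose, bmi, config: GeneratorConfig = GeneratorConfig()):
    """True mean HbA1c change (%) at a weekly dose and baseline BMI."""
    d = np.asarray(dose, float)
    scale = config.emax + config.bmi_interaction * (bmi - config.bmi_ref)
    s = np.where(
        d > 0, d**config.hill / (config.ed50**config.hill + d**config.hill), 0.0
    )
    excess = np.clip(d, None, config.upturn_cap_dose) - config.plateau
    up = np.where(
        d > config.plateau,
        config.upturn * (np.clip(excess, 0.0, None) / 100.0) ** 2,
        0.0,
    )
    out = scale * s + up
    return float(out) if np.isscalar(dose) else out


def _arm_effect(modality, dose, bmi, config: GeneratorConfig) -> float:
    if modality == "UC":
        return 0.0
    if config.effect_model == "modality":
        return config.d_k[modality]
    curve = true_curve(dose, bmi, config)
    if config.effect_model == "dose":
        return curve
    ref = true_curve(config.plateau, config.bmi_ref, config)
    return (config.d_k[modality] / ref) * curve


def _draw_prescription(modality, rng, config) -> Prescription:
    components = None
    if modality == "CT":
        at_mets = round(rng.uniform(4.0, 7.0), 1)
        rt_mets = round(rng.uniform(3.0, 6.0), 1)
        mets = (at_mets + rt_mets) / 2.0
    else:
        lo, hi = _MET_RANGES[modality]
        mets = round(rng.uniform(lo, hi), 1)
    spw = int(rng.integers(2, 6)) if modality != "HIIT" else int(rng.integers(2, 5))
    target = rng.uniform(250.0, 1150.0)
    with_ancillary = rng.uniform() < 0.5
    if with_ancillary:
        # warm-up and cool-down contribute 2.5 METs x 20 min per session;
        # the drawn target is the TOTAL weekly dose, ancillary included
        target = max(target - 2.5 * 20.0 * spw, 100.0)
    minutes = float(np.clip(round(target / (mets * spw)), 10, 90))
    if modality == "CT":
        half = minutes / 2.0
        components = [Component("AT", at_mets, half), Component("RT", rt_mets, half)]
        main = Phase("main", mets, minutes)
    else:
        main = Phase("main", mets, minutes)
    if with_ancillary:
        phases = [Phase("warmup", 2.5, 10.0), main, Phase("cooldown", 2.5, 10.0)]
    else:
        phases = [main]
    return Prescription(phases=phases, sessions_per_week=float(spw), components=components)


def _grid(config) -> np.ndarray:
    return np.arange(0.0, config.grid_max + 1, config.grid_step)


def generate_network(
    config: GeneratorConfig = GeneratorConfig(), seed: int = 0
) -> tuple[list[StudyArm], list[StudyMeta], TruthLedger]:
    """Generate a full synthetic network with its truth ledger."""
    config.validate()
    rng = np.random.default_rng([int(seed) % 2**31, 13])
    mods = list(config.modality_mix)
    probs = np.array([config.modality_mix[m] for m in mods])
    arms: list[StudyArm] = []
    metas: list[StudyMeta] = []
    truth_rows = []
    edge_counts: dict = {}
    n_participants = 0
    for t in range(config.n_trials):
        sid = f"S{t + 1:02d}"
        n_active = 2 if rng.uniform() < config.p_three_arm else 1
        picked = [str(m) for m in rng.choice(mods, size=n_active, replace=False, p=probs)]
        if rng.uniform() < config.p_uc_anchor or n_active == 1:
            trial_mods = picked + ["UC"]
        else:
            trial_mods = picked
        bmi = float(
            np.clip(rng.normal(config.bmi_mean, config.bmi_sd), *config.bmi_range)
        )
        meta = StudyMeta(
            study_id=sid,
            year=int(rng.integers(2005, 2025)),
            country=str(rng.choice(_COUNTRIES, p=[0.66] + [0.34 / 11] * 11)),
            mean_age=round(float(rng.normal(config.age_mean, config.age_sd)), 1),
            pct_male=round(float(np.clip(rng.normal(config.pct_male_mean, 10), 0, 100)), 1),
            baseline_bmi=round(bmi, 2),
            baseline_hba1c=round(
                float(np.clip(rng.normal(config.baseline_hba1c_mean,
                                         config.baseline_hba1c_sd), 5.7, 6.4)), 2
            ),
            weeks=int(rng.choice([8, 12, 16, 24, 36, 52])),
        )
        metas.append(meta)
        rob = str(rng.choice(["low", "some_concerns", "high"], p=config.rob_probs))
        drift = rng.normal(config.drift_mean, config.drift_sd)
        u_trial = rng.normal(0.0, config.tau / np.sqrt(2.0))
        sorted_mods = sorted(trial_mods)
        for i, a in enumerate(sorted_mods):
            for b in sorted_mods[i + 1:]:
                key = frozenset({a, b})
                edge_counts[key] = edge_counts.get(key, 0) + 1
        for mod in trial_mods:
            if mod == "UC":
                rx, dosev, eff = None, 0.0, 0.0
            else:
                rx = _draw_prescription(mod, rng, config)
                dosev = weekly_dose(rx)
                eff = _arm_effect(mod, dosev, bmi, config)
                eff += u_trial + rng.normal(0.0, config.tau / np.sqrt(2.0))
            true_mean = drift + eff
            sd = max(0.2, rng.normal(config.outcome_sd, config.outcome_sd_jitter))
            assigned = int(
                np.clip(
                    round(np.exp(rng.normal(np.log(config.assigned_median),
                                            config.assigned_log_sd))),
                    *config.n_range,
                )
            )
            p_complete = config.adherence_rate
            if mod != "UC":
                odds = p_complete / (1 - p_complete) * config.adherence_or.get(mod, 1.0)
                p_complete = odds / (1 + odds)
            completers = int(rng.binomial(assigned, p_complete))
            n = max(completers, 8)
            obs_mean = float(true_mean + rng.normal(0.0, sd / np.sqrt(n)))
            kwargs = dict(
                study_id=sid, modality=mod, n=n,
                completers=completers, assigned=assigned,
                prescription=rx, rob=rob,
            )
            if rng.uniform() < config.p_report_change:
                kwargs.update(change_mean=round(obs_mean, 4), change_sd=round(sd, 4))
            else:
                base = float(rng.normal(meta.baseline_hba1c, 0.05))
                # equal baseline/post SDs reproduce sd exactly at r = 0.5
                kwargs.update(
                    baseline_mean=round(base, 4), baseline_sd=round(sd, 4),
                    post_mean=round(base + obs_mean, 4), post_sd=round(sd, 4),
                )
            arm = StudyArm(**kwargs)
            arm.validate()
            arms.append(arm)
            n_participants += n
            truth_rows.append(
                {
                    "study_id": sid, "modality": mod, "dose": dosev,
                    "bmi": bmi, "true_effect": eff, "true_mean": true_mean,
                }
            )
    grid = _grid(config)
    curve_values = {"overall": true_curve(grid, config.bmi_ref, config)}
    strata = {"normal": 22.0, "overweight": 26.0, "obesity": 29.5}
    minimal_clinical = {}
    for name, b in strata.items():
        vals = true_curve(grid, b, config)
        curve_values[name] = vals
        hit = grid[(grid > 0) & (vals <= -0.2)]
        minimal_clinical[name] = float(hit[0]) if hit.size else None
    ledger = TruthLedger(
        seed=seed,
        d_k=dict(config.d_k),
        tau=config.tau,
        effect_model=config.effect_model,
        arms=pd.DataFrame(truth_rows),
        curve_grid=grid,
        curve_values=curve_values,
        true_optimal=float(grid[int(np.argmin(curve_values["overall"]))]),
        true_minimal_clinical=minimal_clinical,
        n_trials=config.n_trials,
        n_arms=len(arms),
        n_participants=n_participants,
        edge_counts=edge_counts,
    )
    return arms, metas, ledger


def generate_loop_contrasts(
    n_per_design: int = 4,
    d_a: float = -0.4,
    d_b: float = -0.2,
    tau: float = 0.1,
    n_per_arm: int = 60,
    sd: float = 0.45,
    gap: float = 0.0,
    seed: int = 0,
) -> list[Contrast]:
    """Two-arm trials forming an (A, B, UC) loop, for consistency checks.

    ``gap`` shifts the direct A-vs-B trials away from ``d_a − d_b``, creating
    direct-indirect disagreement of a known size.
    """
    rng = np.random.default_rng([int(seed) % 2**31, 29])
    out: list[Contrast] = []
    designs = [("A", "UC", d_a), ("B", "UC", d_b), ("A", "B", d_a - d_b + gap)]
    k = 0
    for treat, ref, truth in designs:
        for _ in range(n_per_design):
            k += 1
            se = sd * np.sqrt(2.0 / n_per_arm)
            md = truth + rng.normal(0.0, tau) + rng.normal(0.0, se)
            out.append(
                Contrast(
                    study_id=f"L{k:02d}", treatment=treat, reference=ref,
                    md=float(md), se=float(se), n_t=n_per_arm, n_r=n_per_arm,
                    ref_var=sd**2 / n_per_arm,
                )
            )
    return out
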