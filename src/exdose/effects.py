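"""Analysis-ready relative effects and adherence data from arm summaries.

Change scores are the analysis outcome.  When a trial reports only baseline
and post summaries, the change mean is ``post − baseline`` and its SD is
imputed as

    SD_change = sqrt(SD_baseline² + SD_post² − 2 r SD_baseline SD_post)

with pre-post correlation r = 0.5 by default (sensitivity grid 0.3/0.5/0.7).
SDs reported indirectly convert via SE, 95% CI or t statistics.

Relative effects are mean differences of change scores against the trial's
reference arm (usual care when present, else the alphabetically first
modality); multi-arm trials keep the shared-reference structure, and the
reference arm's sampling variance is recorded so downstream models can
induce the within-trial correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .data import DataError, StudyArm

__all__ = [
    "Contrast",
    "CorrelationAssumption",
    "sd_change",
    "sd_from_se",
    "sd_from_ci",
    "se_from_t",
    "arm_change",
    "build_contrasts",
    "adherence_table",
    "summary_odds_ratio",
]

DEFAULT_R = 0.5
SENSITIVITY_R = (0.3, 0.5, 0.7)


@dataclass(frozen=True)
class CorrelationAssumption:
    """Assumed correlation between baseline and post HbA1c measurements."""

    r: float = DEFAULT_R

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class Contrast:
    """Relative effect (mean difference of change scores) in one trial."""

    study_id: str
    treatment: str
    reference: str
    md: float
    se: float
    n_t: int
    n_r: int
    #: sampling variance of the shared reference arm's mean change;
    #: the within-trial covariance of two contrasts sharing that arm.
    ref_var: float = 0.0

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("contrast SE must be positive")
        if self.treatment == self.reference:
            raise ValueError("treatment and reference must differ")

    @property
    def comparison(self) -> tuple[str, str]:
        return (self.treatment, self.reference)


def sd_change(sd_baseline: float, sd_post: float, r: float = DEFAULT_R) -> float:
    """SD of the pre-post change from the two time-point SDs."""
    if sd_baseline <= 0 or sd_post <= 0:
        raise ValueError("SDs must be positive")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    v = sd_baseline**2 + sd_post**2 - 2.0 * r * sd_baseline * sd_post
    return math.sqrt(max(v, 0.0))


def sd_from_se(se: float, n: int) -> float:
    """SD from a standard error of the mean."""
    return se * math.sqrt(n)


def sd_from_ci(lower: float, upper: float, n: int, z: float = 1.959964) -> float:
    """SD from a 95% CI of a mean, assuming a normal reference distribution."""
    if upper < lower:
        raise ValueError("CI bounds reversed")
    return math.sqrt(n) * (upper - lower) / (2.0 * z)


def se_from_t(md: float, t: float) -> float:
    """SE of a mean difference from its t statistic."""
    if t == 0:
        raise ValueError("t statistic must be nonzero")
    return abs(md) / abs(t)


def arm_change(arm: StudyArm, r: float = DEFAULT_R) -> tuple[float, float]:
    """(mean change, SD of change) for one arm.

    Reported change summaries pass through verbatim; otherwise the change is
    reconstructed from baseline and post summaries with the correlation
    assumption.
    """
    if arm.has_change_pair:
        return float(arm.change_mean), float(arm.change_sd)
    if arm.has_prepost_pairs:
        mean = float(arm.post_mean) - float(arm.baseline_mean)
        sd = sd_change(float(arm.baseline_sd), float(arm.post_sd), r)
        if sd <= 0:
            raise DataError(
                f"{arm.study_id}/{arm.modality}: imputed change SD is zero"
            )
        return mean, sd
    raise DataError(
        f"{arm.study_id}/{arm.modality}: no usable outcome representation"
    )


def _reference_arm(arms: list[StudyArm]) -> StudyArm:
    by_mod = {a.modality: a for a in arms}
    if "UC" in by_mod:
        return by_mod["UC"]
    return by_mod[min(by_mod)]


def build_contrasts(arms: list[StudyArm], r: float = DEFAULT_R) -> list[Contrast]:
    """Contrasts of every non-reference arm against the trial reference.

    Within a multi-arm trial all contrasts share the reference arm, so
    md(A vs B) = md(A vs UC) − md(B vs UC) holds exactly at construction.
    """
    if len(arms) < 2:
        raise DataError("a trial needs at least 2 arms to form contrasts")
    mods = [a.modality for a in arms]
    if len(set(mods)) != len(mods):
        raise DataError(f"{arms[0].study_id}: duplicate modality within trial")
    ref = _reference_arm(arms)
    ref_mean, ref_sd = arm_change(ref, r)
    ref_var = ref_sd**2 / ref.n
    out = []
    for arm in arms:
        if arm is ref:
            continue
        mean, sd = arm_change(arm, r)
        se = math.sqrt(sd**2 / arm.n + ref_var)
        out.append(
            Contrast(
                study_id=arm.study_id,
                treatment=arm.modality,
                reference=ref.modality,
                md=mean - ref_mean,
                se=se,
                n_t=arm.n,
                n_r=ref.n,
                ref_var=ref_var,
            )
        )
    return out


def adherence_table(arms: list[StudyArm]) -> pd.DataFrame:
    """Binomial adherence data (completers of assigned) per arm.

    Returns one row per arm with events/totals keyed by study and modality;
    arms with a zero cell (no completer or no dropout) are flagged for
    continuity handling in summary odds ratios.
    """
    records = []
    for arm in arms:
        if arm.completers is None or arm.assigned is None:
            continue
        if arm.assigned == 0:
            raise DataError(f"{arm.study_id}/{arm.modality}: empty arm (assigned=0)")
        if arm.completers > arm.assigned:
            raise DataError(f"{arm.study_id}/{arm.modality}: completers > assigned")
        records.append(
            {
                "study_id": arm.study_id,
                "modality": arm.modality,
                "events": int(arm.completers),
                "total": int(arm.assigned),
                "zero_cell": arm.completers in (0, arm.assigned),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["study_id", "modality", "events", "total", "zero_cell"]
    )


def summary_odds_ratio(
    events_t: int, total_t: int, events_r: int, total_r: int,
    continuity: float = 0.5,
) -> float:
    """Completion odds ratio for one 2×2 table, with continuity correction
    applied only when a zero cell is present."""
    a, b = events_t, total_t - events_t
    c, d = events_r, total_r - events_r
    if 0 in (a, b, c, d):
        a, b, c, d = (x + continuity for x in (a, b, c, d))
    return (a * d) / (b * c)
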