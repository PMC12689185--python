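"""Minimally contextualised classification of interventions.

Effects are HbA1c changes versus usual care (negative = reduction).  The
MCID is a 0.2% reduction; an interval is

* ``not_significant`` when its upper bound reaches 0,
* ``statistical_only`` when it excludes 0 but crosses back above the MCID,
* ``clinical_and_statistical`` when it lies entirely beyond the MCID.

Interventions are then grouped by certainty of evidence (supplied as input
from a CINeMA-style appraisal, never computed here) into a high block
(high/moderate) and a low block (low/very low), and within each block
classified as among the most effective (category 2: point estimate beyond
the MCID, interval excluding 0, and SUCRA at least 0.5), intermediately
effective (category 1: significant but short of category 2), or least
effective (interval covering 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CertaintyRating",
    "EFFECT_FLAGS",
    "mcid_flag",
    "classify_interventions",
]

MCID = -0.2
CERTAINTY_LEVELS = ("high", "moderate", "low", "very_low")
EFFECT_FLAGS = ("not_significant", "statistical_only", "clinical_and_statistical")


@dataclass(frozen=True)
class CertaintyRating:
    comparison: str
    rating: str

    def __post_init__(self) -> None:
        if self.rating not in CERTAINTY_LEVELS:
            raise ValueError(f"unknown certainty rating {self.rating!r}")


def mcid_flag(mean: float, lo: float, hi: float, mcid: float = MCID) -> str:
    """Deterministic clinical-relevance flag for one (mean, 95% interval)."""
    if not (lo <= mean <= hi):
        raise ValueError("malformed interval: requires lo <= mean <= hi")
    if hi >= 0:
        return "not_significant"
    if hi > mcid:
        return "statistical_only"
    return "clinical_and_statistical"


def classify_interventions(
    effects: dict,
    sucra: dict,
    certainty: dict,
    mcid: float = MCID,
) -> pd.DataFrame:
    """Categorise interventions by effectiveness within certainty blocks.

    Parameters
    ----------
    effects : dict modality -> (mean, lo, hi) versus usual care.
    sucra : dict modality -> SUCRA score in [0, 1].
    certainty : dict modality -> rating (high/moderate/low/very_low).
    """
    rows = []
    for mod, (mean, lo, hi) in effects.items():
        rating = certainty.get(mod)
        flag = mcid_flag(mean, lo, hi, mcid)
        if rating is None:
            block, category = "unclassified", "unclassified"
        else:
            if rating not in CERTAINTY_LEVELS:
                raise ValueError(f"unknown certainty rating {rating!r}")
            block = "high_certainty" if rating in ("high", "moderate") else "low_certainty"
            s = sucra.get(mod, 0.0)
            if flag == "not_significant":
                category = "least_effective"
            elif mean <= mcid and s >= 0.5:
                category = "category_2_most_effective"
            else:
                category = "category_1_intermediate"
        rows.append(
            {
                "modality": mod,
                "mean": mean,
                "cri_low": lo,
                "cri_high": hi,
                "sucra": sucra.get(mod),
                "certainty": rating,
                "flag": flag,
                "certainty_block": block,
                "category": category,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["certainty_block", "category", "mean"], ignore_index=True
    )
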