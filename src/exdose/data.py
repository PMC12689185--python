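"""Study-level data model, table IO, MET lookup and network geometry.

The unit of input is one trial arm (long format, one CSV row per arm):
outcome summaries of HbA1c (%) at baseline/post or as pre-post change, the
analysed/assigned counts used for adherence, a risk-of-bias rating, and the
exercise prescription flattened into phase columns.  Study-level covariates
(age, %male, baseline BMI, baseline HbA1c, intervention weeks, …) are
repeated on each row of a trial and de-duplicated into :class:`StudyMeta`.

Column schema of the study table (mandatory columns are starred):

    study_id*, modality*, n*, baseline_mean, baseline_sd, post_mean, post_sd,
    change_mean, change_sd, completers, assigned, rob, year, country,
    mean_age, pct_male, baseline_bmi, baseline_hba1c, weeks,
    sessions_per_week, warmup_mets, warmup_minutes, main_mets, main_minutes,
    cooldown_mets, cooldown_minutes, ct_at_mets, ct_at_minutes, ct_rt_mets,
    ct_rt_minutes

Modality labels are the fixed five-category exercise taxonomy plus usual
care: AT, RT, CT, HIIT, MBT, UC.  Unknown labels are an error, never
coerced.  A small Compendium-style MET code lookup is bundled for the codes
exercised in tests; a full lookup table can be supplied via the same CSV
format (code, description, mets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources as _resources

import networkx as nx
import pandas as pd

from .dose import Component, Phase, Prescription

__all__ = [
    "MODALITIES",
    "ROB_LEVELS",
    "SchemaError",
    "DataError",
    "StudyArm",
    "StudyMeta",
    "MetTable",
    "NetworkGeometry",
    "read_study_table",
    "write_study_table",
    "load_met_lookup",
    "network_geometry",
]

MODALITIES = ("AT", "RT", "CT", "HIIT", "MBT", "UC")
ROB_LEVELS = ("low", "some_concerns", "high")


class SchemaError(ValueError):
    """Input table violates the documented column schema."""


class DataError(ValueError):
    """A row or record violates a data invariant."""


def _isnum(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


@dataclass
class StudyArm:
    """One trial arm with outcome summaries and prescription."""

    study_id: str
    modality: str
    n: int
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    post_mean: float | None = None
    post_sd: float | None = None
    change_mean: float | None = None
    change_sd: float | None = None
    completers: int | None = None
    assigned: int | None = None
    prescription: Prescription | None = None
    rob: str = "some_concerns"

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise DataError(f"{self.study_id}: unknown modality {self.modality!r}")
        if self.n < 1:
            raise DataError(f"{self.study_id}: arm size n must be >= 1")
        for name in ("baseline_sd", "post_sd", "change_sd"):
            v = getattr(self, name)
            if _isnum(v) and v <= 0:
                raise DataError(f"{self.study_id}: {name} must be > 0")
        if not (self.has_change_pair or self.has_prepost_pairs):
            raise DataError(
                f"{self.study_id}/{self.modality}: needs a (change_mean, change_sd) "
                "pair or baseline+post pairs"
            )
        if _isnum(self.completers) and _isnum(self.assigned):
            if self.completers > self.assigned:
                raise DataError(f"{self.study_id}: completers > assigned")
        if self.rob not in ROB_LEVELS:
            raise DataError(f"{self.study_id}: unknown risk-of-bias label {self.rob!r}")
        if self.modality == "UC" and self.prescription is not None:
            raise DataError(f"{self.study_id}: UC arm must not carry a prescription")

    @property
    def has_change_pair(self) -> bool:
        return _isnum(self.change_mean) and _isnum(self.change_sd)

    @property
    def has_prepost_pairs(self) -> bool:
        return all(
            _isnum(getattr(self, f))
            for f in ("baseline_mean", "baseline_sd", "post_mean", "post_sd")
        )

    @property
    def needs_imputation(self) -> bool:
        """True when the change SD must be imputed from baseline/post SDs."""
        return not self.has_change_pair and self.has_prepost_pairs


@dataclass
class StudyMeta:
    """Study-level covariates shared by all arms of one trial."""

    study_id: str
    year: int | None = None
    country: str | None = None
    mean_age: float | None = None
    pct_male: float | None = None
    baseline_bmi: float | None = None
    baseline_hba1c: float | None = None
    weeks: int | None = None

    def validate(self) -> None:
        if _isnum(self.baseline_bmi) and not (14 <= self.baseline_bmi <= 60):
            raise DataError(f"{self.study_id}: baseline BMI outside [14, 60]")
        if _isnum(self.baseline_hba1c) and not (4 <= self.baseline_hba1c <= 9):
            raise DataError(f"{self.study_id}: baseline HbA1c outside [4, 9]")
        if _isnum(self.pct_male) and not (0 <= self.pct_male <= 100):
            raise DataError(f"{self.study_id}: pct_male outside [0, 100]")
        if self.weeks is not None and self.weeks < 1:
            raise DataError(f"{self.study_id}: weeks must be positive")


@dataclass
class MetTable:
    """Activity-code → METs lookup."""

    rows: pd.DataFrame  # columns: code, description, mets

    def __post_init__(self) -> None:
        codes = self.rows["code"]
        if codes.duplicated().any():
            dupes = sorted(codes[codes.duplicated()].unique())
            raise SchemaError(f"duplicate MET codes: {dupes}")
        mets = self.rows["mets"]
        if ((mets < 0.9) | (mets > 23)).any():
            raise DataError("METs values must lie in [0.9, 23]")
        self._index = dict(zip(codes, mets))

    def lookup(self, code: str) -> float:
        try:
            return float(self._index[str(code)])
        except KeyError:
            raise KeyError(f"unknown MET code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return str(code) in self._index

    def __len__(self) -> int:
        return len(self._index)


@dataclass
class NetworkGeometry:
    """Treatment-network structure implied by the trial designs."""

    nodes: frozenset
    edges: dict  # frozenset({a, b}) -> number of trials with that direct pair
    connected: bool
    n_trials: int = 0

    def edge_count(self, a: str, b: str) -> int:
        return self.edges.get(frozenset({a, b}), 0)


_ARM_COLUMNS = [
    "study_id", "modality", "n",
    "baseline_mean", "baseline_sd", "post_mean", "post_sd",
    "change_mean", "change_sd", "completers", "assigned", "rob",
]
_META_COLUMNS = [
    "year", "country", "mean_age", "pct_male",
    "baseline_bmi", "baseline_hba1c", "weeks",
]
_RX_COLUMNS = [
    "sessions_per_week",
    "warmup_mets", "warmup_minutes", "main_mets", "main_minutes",
    "cooldown_mets", "cooldown_minutes",
    "ct_at_mets", "ct_at_minutes", "ct_rt_mets", "ct_rt_minutes",
]
MANDATORY_COLUMNS = ("study_id", "modality", "n")


def _row_prescription(row: pd.Series) -> Prescription | None:
    if row["modality"] == "UC":
        return None
    phases = []
    for role in ("warmup", "main", "cooldown"):
        m, mins = row.get(f"{role}_mets"), row.get(f"{role}_minutes")
        if _isnum(mins) and mins > 0:
            phases.append(Phase(role, m if _isnum(m) else 2.5, float(mins)))
    components = None
    if _isnum(row.get("ct_at_minutes")) or _isnum(row.get("ct_rt_minutes")):
        components = []
        for sub in ("at", "rt"):
            m, mins = row.get(f"ct_{sub}_mets"), row.get(f"ct_{sub}_minutes")
            if _isnum(mins) and mins > 0:
                components.append(Component(sub.upper(), float(m), float(mins)))
    spw = row.get("sessions_per_week")
    if not _isnum(spw) and not phases and components is None:
        return None
    return Prescription(
        phases=phases,
        sessions_per_week=float(spw) if _isnum(spw) else 0.0,
        components=components,
    )


def read_study_table(path) -> tuple[list[StudyArm], list[StudyMeta]]:
    """Read and validate a long-format study table.

    Returns typed arm records plus one :class:`StudyMeta` per trial.  Missing
    optional fields stay ``None``; arms whose change SD must be imputed are
    flagged via :attr:`StudyArm.needs_imputation`, never dropped.
    """
    df = pd.read_csv(path, dtype={"study_id": str, "modality": str, "country": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    arms: list[StudyArm] = []
    metas: dict[str, StudyMeta] = {}
    for i, row in df.iterrows():
        sid = row["study_id"]
        kwargs = {}
        for col in _ARM_COLUMNS[2:]:
            v = row.get(col)
            if col in ("n", "completers", "assigned"):
                if _isnum(v):
                    try:
                        kwargs[col] = int(v)
                    except (TypeError, ValueError):
                        raise DataError(f"row {i} (study {sid}): non-numeric {col}={v!r}")
            elif col == "rob":
                kwargs[col] = v if isinstance(v, str) else "some_concerns"
            else:
                if _isnum(v):
                    try:
                        kwargs[col] = float(v)
                    except (TypeError, ValueError):
                        raise DataError(f"row {i} (study {sid}): non-numeric {col}={v!r}")
                else:
                    kwargs[col] = None
        if "n" not in kwargs:
            raise DataError(f"row {i} (study {sid}): missing or non-numeric n")
        arm = StudyArm(
            study_id=sid,
            modality=row["modality"],
            prescription=_row_prescription(row),
            **kwargs,
        )
        arm.validate()
        arms.append(arm)
        if sid not in metas:
            mkw = {}
            for col in _META_COLUMNS:
                v = row.get(col)
                if col == "country":
                    mkw[col] = v if isinstance(v, str) else None
                elif col in ("year", "weeks"):
                    mkw[col] = int(v) if _isnum(v) else None
                else:
                    mkw[col] = float(v) if _isnum(v) else None
            meta = StudyMeta(study_id=sid, **mkw)
            meta.validate()
            metas[sid] = meta
    return arms, list(metas.values())


def write_study_table(arms, metas, path) -> None:
    """Write arms + metas back to the long CSV schema (round-trip safe)."""
    meta_by_id = {m.study_id: m for m in metas}
    records = []
    for arm in arms:
        rec = {c: getattr(arm, c) for c in _ARM_COLUMNS}
        meta = meta_by_id.get(arm.study_id)
        if meta is not None:
            rec.update({c: getattr(meta, c) for c in _META_COLUMNS})
        rx = arm.prescription
        if rx is not None:
            rec["sessions_per_week"] = rx.sessions_per_week
            for ph in rx.phases:
                rec[f"{ph.role}_mets"] = ph.mets
                rec[f"{ph.role}_minutes"] = ph.minutes
            for comp in rx.components or []:
                key = comp.sub_modality.lower()
                rec[f"ct_{key}_mets"] = comp.mets
                rec[f"ct_{key}_minutes"] = comp.minutes
        records.append(rec)
    cols = _ARM_COLUMNS + _META_COLUMNS + _RX_COLUMNS
    pd.DataFrame.from_records(records, columns=cols).to_csv(path, index=False)


def load_met_lookup(path=None) -> MetTable:
    """Load a MET code lookup CSV (code, description, mets).

    With no path, loads the bundled subset covering the codes used in the
    package's own examples and tests.
    """
    if path is None:
        ref = _resources.files("exdose.resources") / "met_codes.csv"
        with ref.open("rb") as fh:
            df = pd.read_csv(fh, dtype={"code": str})
    else:
        df = pd.read_csv(path, dtype={"code": str})
    for col in ("code", "mets"):
        if col not in df.columns:
            raise SchemaError(f"MET lookup missing column {col!r}")
    if "description" not in df.columns:
        df["description"] = ""
    return MetTable(rows=df[["code", "description", "mets"]])


def network_geometry(arms) -> NetworkGeometry:
    """Node set, per-edge trial counts and connectivity of the network.

    Every unordered modality pair co-occurring in a trial contributes one
    direct comparison; a disconnected network is reported (not raised) so the
    NMA layer can refuse explicitly.
    """
    by_study: dict[str, set] = {}
    for arm in arms:
        by_study.setdefault(arm.study_id, set()).add(arm.modality)
    if not by_study:
        raise DataError("no trials supplied")
    g = nx.Graph()
    edges: dict[frozenset, int] = {}
    for sid, mods in by_study.items():
        if len(mods) < 2:
            raise DataError(f"trial {sid} contributes fewer than 2 arms")
        g.add_nodes_from(mods)
        mods_sorted = sorted(mods)
        for i, a in enumerate(mods_sorted):
            for b in mods_sorted[i + 1:]:
                key = frozenset({a, b})
                edges[key] = edges.get(key, 0) + 1
                g.add_edge(a, b)
    return NetworkGeometry(
        nodes=frozenset(g.nodes),
        edges=edges,
        connected=nx.is_connected(g),
        n_trials=len(by_study),
    )
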