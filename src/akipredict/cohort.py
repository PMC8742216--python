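"""Admissions / lab-event data model, CKD-EPI eGFR, and the exclusion cascade.

The analyzable cohort is produced by five rules applied in order, the
first match recorded as the exclusion reason:

1. ``short_stay``            — discharged within 48 h of admission
2. ``community_aki``         — earliest AKI onset within 48 h of admission
3. ``ckd5``                  — ESKD diagnosis code, admission eGFR < 15
                               mL/min/1.73 m2, or dialysis-access procedure code
4. ``prior_rrt_no_recovery`` — prior dialysis / filtration / diafiltration
                               procedure code with admission eGFR < 30
5. ``no_labs``               — no laboratory results at all

"Admission eGFR" uses the first serum creatinine drawn within 48 h of
admission; if no such draw exists the eGFR-based sub-rules cannot fire.
Exclusion operates per admission: a patient excluded in one admission
may be kept in another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .kdigo import AkiEpisode

logger = logging.getLogger(__name__)

UMOL_PER_MGDL = 88.4

LAB_COLUMNS = ["admission_id", "patient_id", "analyte", "value", "unit", "timestamp"]
ADMISSION_COLUMNS = ["admission_id", "patient_id", "admit_time", "discharge_time",
                     "age_years", "sex", "diagnosis_codes", "procedure_codes"]

EXCLUSION_REASONS = ("short_stay", "community_aki", "ckd5",
                     "prior_rrt_no_recovery", "no_labs")


@dataclass(frozen=True)
class LabEvent:
    admission_id: str
    patient_id: str
    analyte: str
    value: float
    unit: str
    timestamp: pd.Timestamp


@dataclass(frozen=True)
class AdmissionRecord:
    admission_id: str
    patient_id: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    age_years: float
    sex: str  # "male" | "female"
    diagnosis_codes: frozenset[str] = frozenset()
    procedure_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.discharge_time <= self.admit_time:
            raise ValueError(f"{self.admission_id}: discharge before admit")
        if self.age_years < 0:
            raise ValueError(f"{self.admission_id}: negative age")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.admission_id}: sex must be male/female")


@dataclass
class CohortConfig:
    """Thresholds and code patterns for the exclusion cascade."""

    short_stay_hours: float = 48.0
    community_aki_hours: float = 48.0
    egfr_ckd5_threshold: float = 15.0
    egfr_recovery_threshold: float = 30.0
    admission_egfr_window_hours: float = 48.0
    eskd_diagnosis_patterns: tuple[str, ...] = (
        "end-stage kidney", "end-stage renal", "end stage kidney",
        "end stage renal", "eskd", "esrd",
    )
    dialysis_access_procedure_patterns: tuple[str, ...] = (
        "peritoneal dialysis catheter", "arteriovenous", "fistuloplasty",
    )
    rrt_procedure_patterns: tuple[str, ...] = (
        "dialysis", "filtration", "diafiltration",
    )
    include_race_coefficient: bool = False
    creatinine_analyte: str = "creatinine_serum"

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("eskd_diagnosis_patterns", "dialysis_access_procedure_patterns",
                    "rrt_procedure_patterns"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class ExclusionResult:
    kept: list[str]
    excluded: dict[str, str]  # admission_id -> first-matching reason
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {r: 0 for r in EXCLUSION_REASONS}
        for reason in self.excluded.values():
            counts[reason] += 1
        self.counts = counts

    def to_report(self) -> dict:
        return {
            "n_input": len(self.kept) + len(self.excluded),
            "n_kept": len(self.kept),
            "n_excluded": len(self.excluded),
            "excluded_by_reason": dict(self.counts),
        }


def read_cohort(
    lab_csv_path: str, admissions_csv_path: str
) -> tuple[list[AdmissionRecord], list[LabEvent], pd.DataFrame]:
    """Parse the two CSV inputs into typed records.

    Returns (admissions, lab_events, rejected_rows).  Malformed lab rows
    (non-finite value, unparseable timestamp) are collected in the
    rejected-rows frame with a reason rather than silently dropped.
    Labs referencing admissions absent from the admissions table raise.
    """
    adm_df = pd.read_csv(admissions_csv_path, dtype={"admission_id": str,
                                                     "patient_id": str})
    _require_columns(adm_df, ADMISSION_COLUMNS, admissions_csv_path)
    lab_df = pd.read_csv(lab_csv_path, dtype={"admission_id": str,
                                              "patient_id": str})
    _require_columns(lab_df, LAB_COLUMNS, lab_csv_path)

    admissions = []
    for row in adm_df.itertuples(index=False):
        admissions.append(AdmissionRecord(
            admission_id=row.admission_id,
            patient_id=row.patient_id,
            admit_time=pd.Timestamp(row.admit_time),
            discharge_time=pd.Timestamp(row.discharge_time),
            age_years=float(row.age_years),
            sex=str(row.sex),
            diagnosis_codes=_split_codes(row.diagnosis_codes),
            procedure_codes=_split_codes(row.procedure_codes),
        ))

    known_ids = {a.admission_id for a in admissions}
    orphans = sorted(set(lab_df["admission_id"]) - known_ids)
    if orphans:
        raise ValueError(
            f"lab events reference admissions missing from the admissions "
            f"table: {orphans[:20]}{'...' if len(orphans) > 20 else ''}")

    values = pd.to_numeric(lab_df["value"], errors="coerce")
    stamps = pd.to_datetime(lab_df["timestamp"], errors="coerce")
    bad_value = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    bad_stamp = stamps.isna().to_numpy()
    bad = bad_value | bad_stamp
    rejected = lab_df.loc[bad].copy()
    rejected["reject_reason"] = np.where(
        bad_value[bad], "non_finite_value", "unparseable_timestamp")
    if len(rejected):
        logger.warning("read_cohort: rejected %d malformed lab rows", len(rejected))

    events = []
    ok = lab_df.loc[~bad]
    for row, val, ts in zip(ok.itertuples(index=False), values[~bad], stamps[~bad]):
        events.append(LabEvent(
            admission_id=row.admission_id, patient_id=row.patient_id,
            analyte=str(row.analyte), value=float(val),
            unit=str(row.unit), timestamp=pd.Timestamp(ts)))
    return admissions, events, rejected


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _split_codes(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(s.strip() for s in str(raw).split(";") if s.strip())


def compute_egfr(creatinine_umol_l: float, age_years: float, sex: str,
                 black: bool = False,
                 include_race_coefficient: bool = False) -> float:
    """CKD-EPI 2009 eGFR in mL/min/1.73 m2 from creatinine in umol/L.

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] (* 1.159 [black], off by default)
    with k = 0.7 (female) / 0.9 (male) and a = -0.329 / -0.411, Scr in
    mg/dL (umol/L divided by 88.4).
    """
    if creatinine_umol_l <= 0 or age_years <= 0:
        raise ValueError("creatinine and age must be positive")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    scr = creatinine_umol_l / UMOL_PER_MGDL
    kappa, alpha = (0.7, -0.329) if sex == "female" else (0.9, -0.411)
    r = scr / kappa
    egfr = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 \
        * 0.993 ** age_years
    if sex == "female":
        egfr *= 1.018
    if black and include_race_coefficient:
        egfr *= 1.159
    return egfr


def creatinine_for_egfr(target_egfr: float, age_years: float, sex: str) -> float:
    """Invert CKD-EPI on the high-creatinine branch (Scr/kappa > 1).

    Only valid for targets below the eGFR at Scr = kappa; used by the
    synthetic generator to plant admissions at a chosen kidney function.
    """
    kappa = 0.7 if sex == "female" else 0.9
    base = 141.0 * 0.993 ** age_years * (1.018 if sex == "female" else 1.0)
    if target_egfr >= base:
        raise ValueError("target eGFR not reachable on the Scr > kappa branch")
    r = (target_egfr / base) ** (-1.0 / 1.209)
    return r * kappa * UMOL_PER_MGDL


def _matches_any(codes: Iterable[str], patterns: Sequence[str]) -> bool:
    low = [c.lower() for c in codes]
    return any(p.lower() in c for c in low for p in patterns)


def admission_egfr(admission: AdmissionRecord, lab_events: Sequence[LabEvent],
                   config: CohortConfig) -> float | None:
    """eGFR from the first creatinine within 48 h of admission, or None."""
    window = pd.Timedelta(hours=config.admission_egfr_window_hours)
    draws = [e for e in lab_events
             if e.analyte == config.creatinine_analyte
             and e.timestamp <= admission.admit_time + window]
    if not draws:
        return None
    first = min(draws, key=lambda e: e.timestamp)
    return compute_egfr(first.value, max(admission.age_years, 1e-9), admission.sex,
                        include_race_coefficient=config.include_race_coefficient)


def apply_exclusions(
    admissions: Sequence[AdmissionRecord],
    lab_events: Sequence[LabEvent],
    aki_episodes: Mapping[str, Sequence[AkiEpisode]],
    config: CohortConfig | None = None,
) -> ExclusionResult:
    """Run the five-rule cascade; first matching rule is the reason."""
    config = config or CohortConfig()
    labs_by_adm: dict[str, list[LabEvent]] = {}
    for e in lab_events:
        labs_by_adm.setdefault(e.admission_id, []).append(e)

    kept: list[str] = []
    excluded: dict[str, str] = {}
    for adm in admissions:
        labs = labs_by_adm.get(adm.admission_id, [])
        episodes = aki_episodes.get(adm.admission_id, [])
        reason = _first_matching_reason(adm, labs, episodes, config)
        if reason is None:
            kept.append(adm.admission_id)
        else:
            excluded[adm.admission_id] = reason
    return ExclusionResult(kept=kept, excluded=excluded)


def _first_matching_reason(adm, labs, episodes, config) -> str | None:
    if adm.discharge_time - adm.admit_time < pd.Timedelta(hours=config.short_stay_hours):
        return "short_stay"
    if episodes:
        earliest = min(e.onset_time for e in episodes)
        if earliest < adm.admit_time + pd.Timedelta(hours=config.community_aki_hours):
            return "community_aki"
    egfr = admission_egfr(adm, labs, config)
    if (_matches_any(adm.diagnosis_codes, config.eskd_diagnosis_patterns)
            or (egfr is not None and egfr < config.egfr_ckd5_threshold)
            or _matches_any(adm.procedure_codes,
                            config.dialysis_access_procedure_patterns)):
        return "ckd5"
    if (_matches_any(adm.procedure_codes, config.rrt_procedure_patterns)
            and egfr is not None and egfr < config.egfr_recovery_threshold):
        return "prior_rrt_no_recovery"
    if not labs:
        return "no_labs"
    return None
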