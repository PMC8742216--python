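"""End-to-end orchestration: label -> exclude -> featurize -> train -> evaluate.

This is the programmatic equivalent of running the CLI steps in order,
used by the experiment scripts and tests.  Split and vocabulary fitting
are leak-free: admissions are anchored first, the 80/10/10 shuffle runs
over anchorable admissions, and normalization statistics come from the
training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import AdmissionRecord, CohortConfig, ExclusionResult, LabEvent
from .evaluation import EvalReport, evaluate
from .features import (FeatureSample, FeatureVocabulary, WindowSpec,
                       anchor_admissions, build_samples, samples_to_arrays,
                       split_cohort)
from .kdigo import AkiEpisode, CreatinineSeries, detect_aki, first_analyzed_episode
from .titv import BaselineModel, TitvConfig, TitvModel, fit_baseline, fit_titv


def label_admissions(
    admissions: Sequence[AdmissionRecord],
    lab_events: Sequence[LabEvent],
    creatinine_analyte: str = "creatinine_serum",
) -> tuple[dict[str, list[AkiEpisode]], dict[str, AkiEpisode]]:
    """KDIGO episodes per admission plus the first analyzed episode.

    Community-acquired first episodes (onset within 48 h of admission)
    are kept in the full episode map (the exclusion cascade needs them)
    but omitted from the first-analyzed map.
    """
    by_adm: dict[str, list[tuple[pd.Timestamp, float]]] = {}
    for e in lab_events:
        if e.analyte == creatinine_analyte:
            by_adm.setdefault(e.admission_id, []).append((e.timestamp, e.value))
    admit_of = {a.admission_id: a.admit_time for a in admissions}
    episodes: dict[str, list[AkiEpisode]] = {}
    first: dict[str, AkiEpisode] = {}
    for aid, pts in by_adm.items():
        pts.sort()
        series = CreatinineSeries(
            aid,
            np.array([np.datetime64(t) for t, _ in pts], dtype="datetime64[ns]"),
            np.array([v for _, v in pts]))
        eps = detect_aki(series)
        if not eps:
            continue
        episodes[aid] = eps
        ep, community = first_analyzed_episode(eps, admit_of[aid])
        if ep is not None and not community:
            first[aid] = ep
    return episodes, first


@dataclass
class PipelineResult:
    exclusions: ExclusionResult
    samples: dict[str, FeatureSample]
    vocabulary: FeatureVocabulary
    splits: tuple[list[str], list[str], list[str]]
    dropped_no_creatinine: list[str]
    models: dict[str, object] = field(default_factory=dict)
    reports: dict[str, EvalReport] = field(default_factory=dict)
    test_scores: dict[str, np.ndarray] = field(default_factory=dict)
    test_labels: np.ndarray | None = None
    test_ids: list[str] = field(default_factory=list)


def run_pipeline(
    admissions: Sequence[AdmissionRecord],
    lab_events: Sequence[LabEvent],
    cohort_config: CohortConfig | None = None,
    window_spec: WindowSpec | None = None,
    titv_config: TitvConfig | None = None,
    model_kinds: Sequence[str] = ("titv",),
    split_seed: int = 0,
    n_boot: int = 500,
    grouped_split: bool = False,
) -> PipelineResult:
    """Run the full study protocol on one cohort and evaluate on test."""
    cohort_config = cohort_config or CohortConfig()
    window_spec = window_spec or WindowSpec()
    titv_config = titv_config or TitvConfig()

    episodes, first = label_admissions(
        admissions, lab_events, cohort_config.creatinine_analyte)
    excl = cohort_mod.apply_exclusions(admissions, lab_events, episodes,
                                       cohort_config)
    anchors, dropped = anchor_admissions(
        admissions, lab_events, first, excl.kept,
        cohort_config.creatinine_analyte)
    usable = [a for a in excl.kept if a in anchors]
    patient_of = {a.admission_id: a.patient_id for a in admissions} \
        if grouped_split else None
    train_ids, valid_ids, test_ids = split_cohort(
        usable, seed=split_seed,
        patient_of=patient_of if grouped_split else None)
    samples, vocab, _ = build_samples(
        admissions, lab_events, first, usable, window_spec,
        train_ids=train_ids,
        creatinine_analyte=cohort_config.creatinine_analyte)

    train = samples_to_arrays(samples, train_ids)
    valid = samples_to_arrays(samples, valid_ids)
    test = samples_to_arrays(samples, test_ids)

    result = PipelineResult(
        exclusions=excl, samples=samples, vocabulary=vocab,
        splits=(train_ids, valid_ids, test_ids),
        dropped_no_creatinine=dropped,
        test_labels=test[2], test_ids=[i for i in test_ids if i in samples])
    for kind in model_kinds:
        if kind == "titv":
            model: object = fit_titv(train, valid, titv_config,
                                     analytes=vocab.analytes)
        else:
            model = fit_baseline(kind, train, valid, titv_config)
        scores = model.predict_proba(test[0], test[1])
        result.models[kind] = model
        result.test_scores[kind] = scores
        if len(np.unique(test[2])) > 1:
            result.reports[kind] = evaluate(
                scores, test[2], n_boot=n_boot, seed=split_seed)
    return result


def frames_to_records(
    admissions_df: pd.DataFrame, labs_df: pd.DataFrame
) -> tuple[list[AdmissionRecord], list[LabEvent]]:
    """Typed records from in-memory generator output (no CSV round trip)."""
    admissions = [
        AdmissionRecord(
            admission_id=str(r.admission_id), patient_id=str(r.patient_id),
            admit_time=pd.Timestamp(r.admit_time),
            discharge_time=pd.Timestamp(r.discharge_time),
            age_years=float(r.age_years), sex=str(r.sex),
            diagnosis_codes=_codes(r.diagnosis_codes),
            procedure_codes=_codes(r.procedure_codes))
        for r in admissions_df.itertuples(index=False)
    ]
    events = [
        LabEvent(str(r.admission_id), str(r.patient_id), str(r.analyte),
                 float(r.value), str(r.unit), pd.Timestamp(r.timestamp))
        for r in labs_df.itertuples(index=False)
    ]
    return admissions, events


def _codes(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(s.strip() for s in str(raw).split(";") if s.strip())
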