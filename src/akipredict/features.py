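"""Windowed featurization of longitudinal labs into supervised samples.

Every kept admission becomes one sample.  The reference time point is
the AKI-defining creatinine (cases) or the final in-hospital creatinine
(controls).  The 48 hours immediately preceding the reference are the
prediction window and are never featurized — this guarantees the alert
lead time.  The 7 days before the prediction window form the feature
window, sectioned into daily bins anchored at the reference; same-bin
values of one analyte are averaged, min-max normalized with statistics
fitted on the training split, and missing cells are zero-imputed with
an explicit observation mask kept alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AdmissionRecord, LabEvent
from .kdigo import AkiEpisode


@dataclass(frozen=True)
class WindowSpec:
    """Prediction lead time and feature-window geometry (hours)."""

    lead_time_h: float = 48.0
    feature_span_h: float = 168.0
    bin_width_h: float = 24.0

    def __post_init__(self) -> None:
        if min(self.lead_time_h, self.feature_span_h, self.bin_width_h) <= 0:
            raise ValueError("all durations must be positive")
        if abs(self.feature_span_h / self.bin_width_h
               - round(self.feature_span_h / self.bin_width_h)) > 1e-9:
            raise ValueError("feature_span must be divisible by bin_width")

    @property
    def n_bins(self) -> int:
        return int(round(self.feature_span_h / self.bin_width_h))


@dataclass
class FeatureVocabulary:
    """Frozen analyte order plus per-feature min/max from the training split."""

    analytes: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, float)
        self.maxs = np.asarray(self.maxs, float)
        if np.any(self.mins > self.maxs):
            raise ValueError("per-feature min must not exceed max")
        self.index = {a: f for f, a in enumerate(self.analytes)}

    def __len__(self) -> int:
        return len(self.analytes)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"analytes": self.analytes,
                       "mins": self.mins.tolist(),
                       "maxs": self.maxs.tolist()}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "FeatureVocabulary":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["analytes"], np.array(raw["mins"]), np.array(raw["maxs"]))


@dataclass
class FeatureSample:
    """One admission's supervised sample: T x F window matrix + label."""

    admission_id: str
    reference_time: pd.Timestamp
    X: np.ndarray  # (T, F) normalized, zero-imputed, in [0, 1]
    M: np.ndarray  # (T, F) binary observation mask
    y: int


def select_reference_time(
    admission: AdmissionRecord,
    first_episode: AkiEpisode | None,
    creatinine_events: Sequence[LabEvent],
) -> tuple[pd.Timestamp, int] | None:
    """Reference time and label; None when a control has no creatinine."""
    if first_episode is not None:
        return first_episode.onset_time, 1
    in_hospital = [e for e in creatinine_events
                   if admission.admit_time <= e.timestamp <= admission.discharge_time]
    if not in_hospital:
        return None
    return max(e.timestamp for e in in_hospital), 0


def bin_events(
    events: Sequence[LabEvent] | pd.DataFrame,
    reference_time: pd.Timestamp,
    spec: WindowSpec,
    vocabulary: FeatureVocabulary,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin means of raw values inside the feature window.

    Bin k (k = 0 oldest .. T-1 most recent) covers the half-open
    interval [ref - lead - (T-k) * width, ref - lead - (T-k-1) * width).
    Events within the prediction window never contribute.
    """
    T, F = spec.n_bins, len(vocabulary)
    sums = np.zeros((T, F))
    counts = np.zeros((T, F))
    if isinstance(events, pd.DataFrame):
        analytes = events["analyte"].to_numpy()
        values = events["value"].to_numpy(float)
        stamps = events["timestamp"].to_numpy(dtype="datetime64[ns]")
    else:
        analytes = np.array([e.analyte for e in events], dtype=object)
        values = np.array([e.value for e in events], float)
        stamps = np.array([np.datetime64(e.timestamp) for e in events],
                          dtype="datetime64[ns]")
    ref = np.datetime64(pd.Timestamp(reference_time))
    hours_before = (ref - stamps) / np.timedelta64(1, "h")
    offset = hours_before - spec.lead_time_h  # position within feature window
    in_window = (offset > 0) & (offset <= spec.feature_span_h)
    for analyte, value, off in zip(analytes[in_window], values[in_window],
                                   offset[in_window]):
        f = vocabulary.index.get(analyte)
        if f is None:
            continue
        # off in (0, span]; bin T-1 holds off in (0, width]
        k = T - 1 - int(np.ceil(off / spec.bin_width_h) - 1)
        sums[k, f] += value
        counts[k, f] += 1
    mask = (counts > 0).astype(float)
    with np.errstate(invalid="ignore"):
        raw = np.where(mask > 0, sums / np.maximum(counts, 1), 0.0)
    return raw, mask


def minmax_normalize(x, feat_min, feat_max):
    """(x - min) / (max - min), clipped to [0, 1]; 0 on a degenerate range."""
    x = np.asarray(x, float)
    feat_min = np.asarray(feat_min, float)
    feat_max = np.asarray(feat_max, float)
    span = feat_max - feat_min
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(span > 0, (x - feat_min) / np.where(span > 0, span, 1.0), 0.0)
    out = np.clip(z, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def impute_missing(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Zero imputation: cells with mask 0 are set exactly to 0."""
    return np.where(M > 0, X, 0.0)


def fit_vocabulary(
    raw_matrices: Sequence[np.ndarray], masks: Sequence[np.ndarray],
    analytes: Sequence[str],
) -> FeatureVocabulary:
    """Per-feature min/max over observed training cells (0/1 fallback)."""
    F = len(analytes)
    mins = np.full(F, np.inf)
    maxs = np.full(F, -np.inf)
    for raw, mask in zip(raw_matrices, masks):
        obs = mask > 0
        for f in range(F):
            col = raw[obs[:, f], f]
            if col.size:
                mins[f] = min(mins[f], col.min())
                maxs[f] = max(maxs[f], col.max())
    unseen = ~np.isfinite(mins)
    mins[unseen], maxs[unseen] = 0.0, 1.0
    return FeatureVocabulary(list(analytes), mins, maxs)


def split_cohort(
    sample_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    patient_of: Mapping[str, str] | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Shuffle and partition sample ids into train/valid/test.

    Sizes are floor(n * f_train) / floor(n * f_valid) / remainder, so
    n = 20,732 with (0.8, 0.1, 0.1) gives 16,585 / 2,073 / 2,074.
    With ``patient_of`` the shuffle is over patients, keeping all of a
    patient's admissions in one split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)
    if patient_of is None:
        order = list(np.array(sample_ids, dtype=object)[rng.permutation(n)])
        n_train = int(np.floor(n * fractions[0]))
        n_valid = int(np.floor(n * fractions[1]))
        return (order[:n_train], order[n_train:n_train + n_valid],
                order[n_train + n_valid:])
    patients = sorted({patient_of[s] for s in sample_ids})
    perm = rng.permutation(len(patients))
    by_patient: dict[str, list[str]] = {}
    for s in sample_ids:
        by_patient.setdefault(patient_of[s], []).append(s)
    train: list[str] = []
    valid: list[str] = []
    test: list[str] = []
    n_train = int(np.floor(n * fractions[0]))
    n_valid = int(np.floor(n * fractions[1]))
    for i in perm:
        group = by_patient[patients[i]]
        if len(train) < n_train:
            train.extend(group)
        elif len(valid) < n_valid:
            valid.extend(group)
        else:
            test.extend(group)
    return train, valid, test


def _group_labs(lab_events: Sequence[LabEvent]) -> dict[str, pd.DataFrame]:
    labs_df = pd.DataFrame({
        "admission_id": [e.admission_id for e in lab_events],
        "analyte": [e.analyte for e in lab_events],
        "value": [e.value for e in lab_events],
        "timestamp": pd.to_datetime([e.timestamp for e in lab_events]),
    }) if lab_events else pd.DataFrame(
        columns=["admission_id", "analyte", "value", "timestamp"])
    return {aid: g for aid, g in labs_df.groupby("admission_id")} if len(labs_df) else {}


def anchor_admissions(
    admissions: Sequence[AdmissionRecord],
    lab_events: Sequence[LabEvent],
    first_episodes: Mapping[str, AkiEpisode],
    kept_ids: Sequence[str],
    creatinine_analyte: str = "creatinine_serum",
) -> tuple[dict[str, tuple[pd.Timestamp, int]], list[str]]:
    """Reference time + label per kept admission; unanchorable ids listed.

    Controls with no in-hospital creatinine have no reference point and
    are dropped (returned, counted, never silently lost).
    """
    adm_by_id = {a.admission_id: a for a in admissions}
    grouped = _group_labs(lab_events)
    anchors: dict[str, tuple[pd.Timestamp, int]] = {}
    dropped: list[str] = []
    for aid in kept_ids:
        adm = adm_by_id[aid]
        g = grouped.get(aid)
        creat = []
        if g is not None:
            gc = g[g["analyte"] == creatinine_analyte]
            creat = [LabEvent(aid, adm.patient_id, creatinine_analyte,
                              float(v), "umol/L", pd.Timestamp(t))
                     for v, t in zip(gc["value"], gc["timestamp"])]
        anchored = select_reference_time(adm, first_episodes.get(aid), creat)
        if anchored is None:
            dropped.append(aid)
        else:
            anchors[aid] = anchored
    return anchors, dropped


def build_samples(
    admissions: Sequence[AdmissionRecord],
    lab_events: Sequence[LabEvent],
    first_episodes: Mapping[str, AkiEpisode],
    kept_ids: Sequence[str],
    spec: WindowSpec | None = None,
    vocabulary: FeatureVocabulary | None = None,
    train_ids: Sequence[str] | None = None,
    creatinine_analyte: str = "creatinine_serum",
) -> tuple[dict[str, FeatureSample], FeatureVocabulary, list[str]]:
    """Full featurization of a kept cohort.

    When ``vocabulary`` is None it is fitted from ``train_ids`` (all
    kept admissions when no split is given yet): analyte order by
    descending prevalence and min/max over the raw binned means.
    Controls without any in-hospital creatinine cannot be anchored and
    are returned in the dropped list.
    """
    spec = spec or WindowSpec()
    grouped = _group_labs(lab_events)
    anchors, dropped = anchor_admissions(
        admissions, lab_events, first_episodes, kept_ids, creatinine_analyte)

    if vocabulary is None:
        fit_ids = [a for a in (train_ids if train_ids is not None else kept_ids)
                   if a in anchors]
        prevalence: dict[str, int] = {}
        for aid in fit_ids:
            g = grouped.get(aid)
            if g is not None:
                for an in set(g["analyte"]):
                    prevalence[an] = prevalence.get(an, 0) + 1
        analytes = sorted(prevalence, key=lambda a: (-prevalence[a], a))
        shape_vocab = FeatureVocabulary(
            analytes, np.zeros(len(analytes)), np.ones(len(analytes)))
        raws, masks = [], []
        for aid in fit_ids:
            g = grouped.get(aid)
            raw, mask = bin_events(
                g if g is not None else [], anchors[aid][0], spec, shape_vocab)
            raws.append(raw)
            masks.append(mask)
        vocabulary = fit_vocabulary(raws, masks, analytes)

    samples: dict[str, FeatureSample] = {}
    for aid, (ref, y) in anchors.items():
        g = grouped.get(aid)
        raw, mask = bin_events(g if g is not None else [], ref, spec, vocabulary)
        X = minmax_normalize(raw, vocabulary.mins[None, :], vocabulary.maxs[None, :])
        X = impute_missing(X, mask)
        samples[aid] = FeatureSample(aid, ref, X, mask, y)
    return samples, vocabulary, dropped


def samples_to_arrays(
    samples: Mapping[str, FeatureSample], ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into (X, M, y) batch arrays in the given id order."""
    ids = [i for i in ids if i in samples]
    X = np.stack([samples[i].X for i in ids])
    M = np.stack([samples[i].M for i in ids])
    y = np.array([samples[i].y for i in ids], float)
    return X, M, y
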