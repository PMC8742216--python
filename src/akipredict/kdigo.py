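"""KDIGO 2012 creatinine-based AKI detection and staging.

AKI is flagged from serial serum creatinine alone (no urine-output
criterion): a point qualifies as AKI-defining if creatinine rose to at
least 1.5x a reference value measured within the preceding 7 days
(relative criterion), or by more than 26.5 umol/L (0.3 mg/dL) over a
reference within the preceding 48 hours (absolute criterion).  The
minimum creatinine inside the widest qualifying look-back window is
taken as the episode's baseline.  Qualifying points within 7 days of an
episode's onset are absorbed into that episode; a fresh qualifying pair
strictly after the prior episode's last qualifying point starts a new
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

RELATIVE_WINDOW_H = 168.0  # 7-day look-back for the 1.5x criterion
ABSOLUTE_WINDOW_H = 48.0   # 48 h look-back for the +26.5 umol/L criterion
RELATIVE_RATIO = 1.5
ABSOLUTE_DELTA_UMOL_L = 26.5
STAGE3_CREATININE_UMOL_L = 353.6
HOSPITAL_ACQUIRED_CUTOFF_H = 48.0


@dataclass(frozen=True)
class CreatinineSeries:
    """Time-ordered serum creatinine (umol/L) for one admission."""

    admission_id: str
    times: np.ndarray   # datetime64[ns], non-decreasing
    values: np.ndarray  # float, > 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype="datetime64[ns]")
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(times).astype("timedelta64[ns]").astype(np.int64) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("creatinine values must be finite and positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_hours(
        cls, hours: Sequence[float], values: Sequence[float],
        admission_id: str = "a", origin: str = "2012-01-01",
    ) -> "CreatinineSeries":
        """Convenience constructor from offsets in hours."""
        t0 = np.datetime64(origin, "ns")
        times = t0 + (np.asarray(hours, float) * 3.6e12).astype("timedelta64[ns]")
        return cls(admission_id, times, np.asarray(values, float))


@dataclass(frozen=True)
class AkiEpisode:
    """A detected KDIGO episode: onset point, baseline, criterion, stage."""

    admission_id: str
    onset_time: pd.Timestamp
    defining_creatinine: float
    baseline_creatinine: float
    baseline_time: pd.Timestamp
    criterion: str  # "relative" | "absolute" | "both"
    stage: int
    last_qualifying_time: pd.Timestamp = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.last_qualifying_time is None:
            object.__setattr__(self, "last_qualifying_time", self.onset_time)


def _hours(a: np.datetime64, b: np.datetime64) -> float:
    return (np.int64(a.astype("datetime64[ns]").view("int64"))
            - np.int64(b.astype("datetime64[ns]").view("int64"))) / 3.6e12


def _point_qualifies(times: np.ndarray, values: np.ndarray, j: int,
                     start: int) -> bool:
    """Does point j form a qualifying pair with any i in [start, j)?"""
    for i in range(start, j):
        gap = _hours(times[j], times[i])
        if gap <= RELATIVE_WINDOW_H and values[j] >= RELATIVE_RATIO * values[i]:
            return True
        if gap <= ABSOLUTE_WINDOW_H and values[j] - values[i] > ABSOLUTE_DELTA_UMOL_L:
            return True
    return False


def _baseline_and_criterion(times: np.ndarray, values: np.ndarray, j: int,
                            start: int) -> tuple[int, str]:
    """Baseline index and criterion flags for defining point j.

    Baseline = minimum creatinine inside the widest qualifying window
    (168 h if the relative criterion has any qualifying partner, else
    48 h), earliest point on ties.  Criterion flags are then judged on
    the (baseline, defining) pair itself, window constraints included.
    """
    rel_any = any(
        _hours(times[j], times[i]) <= RELATIVE_WINDOW_H
        and values[j] >= RELATIVE_RATIO * values[i]
        for i in range(start, j)
    )
    window = RELATIVE_WINDOW_H if rel_any else ABSOLUTE_WINDOW_H
    cand = [i for i in range(start, j) if _hours(times[j], times[i]) <= window]
    b = min(cand, key=lambda i: (values[i], times[i]))
    gap = _hours(times[j], times[b])
    rel = gap <= RELATIVE_WINDOW_H and values[j] >= RELATIVE_RATIO * values[b]
    ab = gap <= ABSOLUTE_WINDOW_H and values[j] - values[b] > ABSOLUTE_DELTA_UMOL_L
    if rel and ab:
        return b, "both"
    return b, ("relative" if rel else "absolute")


def stage_episode(baseline: float, defining: float) -> int:
    """Initial KDIGO stage from the baseline/defining creatinine pair.

    Stage 3: ratio >= 3.0, or defining >= 353.6 umol/L with an absolute
    rise > 26.5; stage 2: ratio >= 2.0; stage 1 otherwise.  The pair
    must qualify under at least one criterion.
    """
    ratio = defining / baseline
    delta = defining - baseline
    if ratio < RELATIVE_RATIO and delta <= ABSOLUTE_DELTA_UMOL_L:
        raise ValueError(
            f"pair (baseline={baseline}, defining={defining}) does not qualify as AKI"
        )
    if ratio >= 3.0 or (defining >= STAGE3_CREATININE_UMOL_L
                        and delta > ABSOLUTE_DELTA_UMOL_L):
        return 3
    if ratio >= 2.0:
        return 2
    return 1


def detect_aki(series: CreatinineSeries) -> list[AkiEpisode]:
    """Scan a creatinine series and return its KDIGO episodes in time order."""
    times, values = series.times, series.values
    n = len(values)
    episodes: list[AkiEpisode] = []
    start = 0  # pairs must begin after the prior episode's last qualifying point
    current: AkiEpisode | None = None
    for j in range(1, n):
        if current is not None:
            if _hours(times[j], current.onset_time.to_datetime64()) <= RELATIVE_WINDOW_H:
                # absorbed if it still qualifies against pre-episode points
                if _point_qualifies(times, values, j, start):
                    current = AkiEpisode(
                        admission_id=current.admission_id,
                        onset_time=current.onset_time,
                        defining_creatinine=current.defining_creatinine,
                        baseline_creatinine=current.baseline_creatinine,
                        baseline_time=current.baseline_time,
                        criterion=current.criterion,
                        stage=current.stage,
                        last_qualifying_time=pd.Timestamp(times[j]),
                    )
                    episodes[-1] = current
                continue
            # episode window over: future pairs must start after its last point
            # .to_datetime64() keeps nanosecond precision; np.datetime64()
            # on a Timestamp truncates to microseconds and can misplace
            # the restart index for sub-microsecond timestamps
            start = int(np.searchsorted(
                times, current.last_qualifying_time.to_datetime64(),
                side="right"))
            current = None
        if j <= start or not _point_qualifies(times, values, j, start):
            continue
        b, criterion = _baseline_and_criterion(times, values, j, start)
        current = AkiEpisode(
            admission_id=series.admission_id,
            onset_time=pd.Timestamp(times[j]),
            defining_creatinine=float(values[j]),
            baseline_creatinine=float(values[b]),
            baseline_time=pd.Timestamp(times[b]),
            criterion=criterion,
            stage=stage_episode(float(values[b]), float(values[j])),
        )
        episodes.append(current)
    return episodes


def first_analyzed_episode(
    episodes: Sequence[AkiEpisode], admit_time: pd.Timestamp
) -> tuple[AkiEpisode | None, bool]:
    """Earliest episode of an admission, with a community-acquired flag.

    The flag is true when onset falls within 48 h of admission; such
    admissions are excluded upstream as community-acquired AKI.
    """
    if not episodes:
        return None, False
    first = min(episodes, key=lambda e: e.onset_time)
    community = (first.onset_time - pd.Timestamp(admit_time)
                 < pd.Timedelta(hours=HOSPITAL_ACQUIRED_CUTOFF_H))
    return first, community


def episodes_to_frame(episodes: Sequence[AkiEpisode],
                      community_flags: dict[str, bool] | None = None) -> pd.DataFrame:
    """Tabular export (episodes.csv schema)."""
    rows = []
    for e in episodes:
        rows.append({
            "admission_id": e.admission_id,
            "onset_time": e.onset_time,
            "baseline": e.baseline_creatinine,
            "defining": e.defining_creatinine,
            "criterion": e.criterion,
            "stage": e.stage,
            "community_flag": (community_flags or {}).get(e.admission_id, False),
        })
    return pd.DataFrame(
        rows, columns=["admission_id", "onset_time", "baseline", "defining",
                       "criterion", "stage", "community_flag"])
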