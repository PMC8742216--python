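"""Independently coded oracles used by the test suite.

These deliberately avoid the library's own code paths: plain Python
loops over hour offsets, literal transcriptions of the KDIGO rules, the
CKD-EPI formula, and Mann-Whitney pair counting.
"""

from __future__ import annotations


# ---------------------------------------------------------------------------
# KDIGO brute-force oracle
# ---------------------------------------------------------------------------

REL_WIN = 168.0
ABS_WIN = 48.0
REL_RATIO = 1.5
ABS_DELTA = 26.5


def _pair_qualifies(hours, values, i, j):
    gap = hours[j] - hours[i]
    rel = gap <= REL_WIN and values[j] >= REL_RATIO * values[i]
    ab = gap <= ABS_WIN and values[j] - values[i] > ABS_DELTA
    return rel, ab


def _any_qualifies(hours, values, j, start):
    for i in range(start, j):
        rel, ab = _pair_qualifies(hours, values, i, j)
        if rel or ab:
            return True
    return False


def oracle_stage(baseline, defining):
    ratio = defining / baseline
    delta = defining - baseline
    if ratio >= 3.0 or (defining >= 353.6 and delta > ABS_DELTA):
        return 3
    if ratio >= 2.0:
        return 2
    return 1


def oracle_detect(hours, values):
    """All-pairs KDIGO episode detection on (hours, values) lists.

    Returns a list of dicts with onset_h, baseline, defining, criterion,
    stage and last_h (last qualifying point absorbed into the episode).
    Semantics transcribed literally: a point j is AKI-defining iff some
    earlier point i (after the prior episode's last qualifying point)
    forms a qualifying pair; the baseline is the minimum creatinine in
    the widest qualifying look-back window (earliest on ties); points
    within 168 h of an onset that still qualify are absorbed.
    """
    n = len(values)
    episodes = []
    start = 0
    cur = None
    for j in range(1, n):
        if cur is not None:
            if hours[j] - cur["onset_h"] <= REL_WIN:
                if _any_qualifies(hours, values, j, start):
                    cur["last_h"] = hours[j]
                continue
            start = sum(1 for h in hours if h <= cur["last_h"])
            cur = None
        if j <= start or not _any_qualifies(hours, values, j, start):
            continue
        rel_any = any(_pair_qualifies(hours, values, i, j)[0]
                      for i in range(start, j))
        window = REL_WIN if rel_any else ABS_WIN
        cand = [i for i in range(start, j) if hours[j] - hours[i] <= window]
        b = min(cand, key=lambda i: (values[i], hours[i]))
        rel, ab = _pair_qualifies(hours, values, b, j)
        criterion = "both" if rel and ab else ("relative" if rel else "absolute")
        cur = {"onset_h": hours[j], "defining": values[j],
               "baseline": values[b], "baseline_h": hours[b],
               "criterion": criterion,
               "stage": oracle_stage(values[b], values[j]),
               "last_h": hours[j]}
        episodes.append(cur)
    return episodes


# ---------------------------------------------------------------------------
# CKD-EPI 2009 oracle
# ---------------------------------------------------------------------------

def oracle_ckdepi(creatinine_umol_l, age_years, sex):
    scr = creatinine_umol_l / 88.4
    if sex == "female":
        kappa, alpha, sex_coef = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_coef = 0.9, -0.411, 1.0
    ratio = scr / kappa
    return (141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** (-1.209)
            * 0.993 ** age_years * sex_coef)


# ---------------------------------------------------------------------------
# AUROC pair-counting oracle
# ---------------------------------------------------------------------------

def oracle_auroc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
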