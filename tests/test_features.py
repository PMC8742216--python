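import numpy as np
import pandas as pd
import pytest

from akipredict.cohort import AdmissionRecord, CohortConfig, LabEvent, apply_exclusions
from akipredict.features import (FeatureVocabulary, WindowSpec, bin_events,
                                 build_samples, impute_missing,
                                 minmax_normalize, samples_to_arrays,
                                 select_reference_time, split_cohort)

REF = pd.Timestamp("2012-03-10")


def _ev(analyte, hours_before_ref, value):
    return LabEvent("A1", "P1", analyte, value, "",
                    REF - pd.Timedelta(hours=hours_before_ref))


def _vocab(analytes):
    n = len(analytes)
    return FeatureVocabulary(list(analytes), np.zeros(n), np.ones(n))


class TestWindowSpec:
    def test_defaults(self):
        spec = WindowSpec()
        assert spec.n_bins == 7

    def test_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(lead_time_h=0)
        with pytest.raises(ValueError):
            WindowSpec(feature_span_h=100, bin_width_h=24)


class TestSelectReferenceTime:
    def _adm(self):
        return AdmissionRecord("A1", "P1", REF - pd.Timedelta(days=10),
                               REF + pd.Timedelta(days=1), 60, "female")

    def test_control_last_creatinine(self):
        events = [_ev("creatinine_serum", h, 70) for h in (200, 100, 30)]
        ref, y = select_reference_time(self._adm(), None, events)
        assert ref == REF - pd.Timedelta(hours=30)
        assert y == 0

    def test_control_without_creatinine_dropped(self):
        assert select_reference_time(self._adm(), None, []) is None


class TestBinEvents:
    def test_boundary_cases(self):
        spec = WindowSpec()
        vocab = _vocab(["creatinine_serum"])
        # 49h before reference: 1h inside the feature window, most recent bin
        raw, mask = bin_events([_ev("creatinine_serum", 49, 70)], REF, spec, vocab)
        assert mask[6, 0] == 1 and raw[6, 0] == 70
        assert mask.sum() == 1
        # 47h before reference: inside the prediction window, never used
        raw, mask = bin_events([_ev("creatinine_serum", 47, 70)], REF, spec, vocab)
        assert mask.sum() == 0

    def test_bin_mean(self):
        spec = WindowSpec()
        vocab = _vocab(["x"])
        raw, mask = bin_events([_ev("x", 50, 10), _ev("x", 60, 20)],
                               REF, spec, vocab)
        assert raw[6, 0] == 15 and mask[6, 0] == 1

    def test_brute_force_oracle(self):
        spec = WindowSpec()
        analytes = ["a", "b", "c"]
        vocab = _vocab(analytes)
        rng = np.random.default_rng(9)
        for _ in range(20):
            events = [_ev(analytes[rng.integers(3)],
                          float(rng.uniform(-24, 300)),
                          float(rng.uniform(1, 100))) for _ in range(120)]
            raw, mask = bin_events(events, REF, spec, vocab)
            T, w, lead = spec.n_bins, spec.bin_width_h, spec.lead_time_h
            for k in range(T):
                for f, tok in enumerate(analytes):
                    # bin k covers hours-before-reference in
                    # (lead + (T-k-1)*w, lead + (T-k)*w]
                    vals = [e.value for e in events
                            if e.analyte == tok
                            and lead + (T - k - 1) * w
                            < (REF - e.timestamp) / pd.Timedelta(hours=1)
                            <= lead + (T - k) * w]
                    if vals:
                        assert mask[k, f] == 1
                        assert raw[k, f] == pytest.approx(np.mean(vals))
                    else:
                        assert mask[k, f] == 0 and raw[k, f] == 0


class TestNormalization:
    @pytest.mark.parametrize("x,lo,hi,out", [
        (5, 0, 10, 0.5), (0, 0, 10, 0.0), (10, 0, 10, 1.0),
        (12, 0, 10, 1.0), (7, 7, 7, 0.0),
    ])
    def test_examples(self, x, lo, hi, out):
        assert minmax_normalize(x, lo, hi) == out

    def test_impute(self):
        X = np.array([[0.2, 0.7], [0.5, 0.9]])
        M = np.array([[1.0, 0.0], [1.0, 1.0]])
        out = impute_missing(X, M)
        assert out[0, 1] == 0.0
        assert out[0, 0] == 0.2 and out[1, 1] == 0.9
        assert np.array_equal(impute_missing(X, np.ones_like(M)), X)


class TestSplit:
    def test_deterministic(self):
        ids = [f"A{i}" for i in range(100)]
        assert split_cohort(ids, seed=4) == split_cohort(ids, seed=4)
        assert split_cohort(ids, seed=4) != split_cohort(ids, seed=5)

    def test_partition(self):
        ids = [f"A{i}" for i in range(101)]
        tr, va, te = split_cohort(ids, seed=0)
        assert sorted(tr + va + te) == sorted(ids)
        assert len(tr) == 80 and len(va) == 10 and len(te) == 11

    def test_grouped_mode(self):
        ids = [f"A{i}" for i in range(60)]
        patient_of = {a: f"P{i // 3}" for i, a in enumerate(ids)}
        tr, va, te = split_cohort(ids, seed=0, patient_of=patient_of)
        split_of = {}
        for name, part in (("tr", tr), ("va", va), ("te", te)):
            for a in part:
                split_of[a] = name
        for i, a in enumerate(ids):
            assert split_of[a] == split_of[ids[3 * (i // 3)]]

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_cohort(["A1", "A2"])


class TestBuildSamples:
    def _cohort(self):
        admit = pd.Timestamp("2012-03-01")
        admissions, events = [], []
        for i in range(12):
            aid = f"A{i}"
            admissions.append(AdmissionRecord(
                aid, f"P{i}", admit, admit + pd.Timedelta(days=12), 60, "male"))
            for d in range(1, 11):
                events.append(LabEvent(aid, f"P{i}", "creatinine_serum",
                                       60.0 + i + d, "umol/L",
                                       admit + pd.Timedelta(days=d)))
                events.append(LabEvent(aid, f"P{i}", "sodium",
                                       130.0 + i, "mmol/L",
                                       admit + pd.Timedelta(days=d, hours=1)))
        return admissions, events

    def test_train_only_normalization(self):
        admissions, events = self._cohort()
        kept = [a.admission_id for a in admissions]
        train_ids = kept[:8]
        _, vocab_all, _ = build_samples(admissions, events, {}, kept,
                                        train_ids=train_ids)
        _, vocab_tr, _ = build_samples(admissions, events, {}, train_ids,
                                       train_ids=train_ids)
        assert vocab_all.analytes == vocab_tr.analytes
        assert np.array_equal(vocab_all.mins, vocab_tr.mins)
        assert np.array_equal(vocab_all.maxs, vocab_tr.maxs)

    def test_bit_identical_rerun(self):
        admissions, events = self._cohort()
        kept = [a.admission_id for a in admissions]
        s1, v1, _ = build_samples(admissions, events, {}, kept, train_ids=kept)
        s2, v2, _ = build_samples(admissions, events, {}, kept, train_ids=kept)
        for aid in kept:
            assert np.array_equal(s1[aid].X, s2[aid].X)
            assert np.array_equal(s1[aid].M, s2[aid].M)

    def test_sample_invariants(self):
        admissions, events = self._cohort()
        kept = [a.admission_id for a in admissions]
        samples, vocab, dropped = build_samples(admissions, events, {}, kept,
                                                train_ids=kept)
        assert dropped == []
        X, M, y = samples_to_arrays(samples, kept)
        assert X.shape == (12, 7, len(vocab))
        assert np.all((X >= 0) & (X <= 1))
        assert np.all(X[M == 0] == 0)
        assert np.all(y == 0)

    def test_leakage_guard(self):
        # an event inside the prediction window never reaches X
        admit = pd.Timestamp("2012-03-01")
        adm = AdmissionRecord("A1", "P1", admit,
                              admit + pd.Timedelta(days=12), 60, "male")
        ref = admit + pd.Timedelta(days=10)
        events = [
            LabEvent("A1", "P1", "creatinine_serum", 70.0, "umol/L",
                     ref - pd.Timedelta(hours=60)),
            LabEvent("A1", "P1", "creatinine_serum", 999.0, "umol/L",
                     ref - pd.Timedelta(hours=24)),
            LabEvent("A1", "P1", "creatinine_serum", 70.0, "umol/L", ref),
        ]
        samples, vocab, _ = build_samples([adm], events, {}, ["A1"],
                                          train_ids=["A1"])
        s = samples["A1"]
        assert s.reference_time == ref
        assert s.M.sum() == 1  # only the -60h draw is featurized
        assert vocab.maxs[vocab.index["creatinine_serum"]] == 70.0
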