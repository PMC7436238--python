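"""Patient-level folds, the Wilcoxon wrapper (vs. an enumeration oracle),
and cross-validation plumbing on a tiny cohort."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pullbacknet.evaluation import (
    make_folds,
    run_cross_validation,
    wilcoxon_signed_rank,
)
from pullbacknet.metrics import mean_label_accuracy
from pullbacknet.models import ModelSpec
from pullbacknet.synthetic import SyntheticConfig, generate_cohort
from pullbacknet.training import AugmentConfig, TrainConfig


class TestMakeFolds:
    def test_even_partition(self):
        pids = [f"P{i}" for i in range(10)]
        folds = make_folds(pids, 5, seed=0)
        assert set(folds) == set(pids)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert np.array_equal(sizes, [2, 2, 2, 2, 2])

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = make_folds([f"P{i}" for i in range(82)], 5, seed=3)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 82

    def test_seeded_determinism_and_duplicate_ids(self):
        pids = ["P1", "P2", "P3", "P2", "P1"]  # repeated videos of a patient
        a = make_folds(pids, 2, seed=9)
        b = make_folds(pids, 2, seed=9)
        assert a == b
        assert set(a) == {"P1", "P2", "P3"}

    def test_errors(self):
        with pytest.raises(ValueError):
            make_folds(["P1", "P2", "P3"], 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(["P1", "P2"], 3, seed=0)


def exact_two_sided_p(diffs):
    """Enumeration oracle: distribution of W+ over all sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    obs = ranks[diffs > 0].sum()
    ws = [np.array(signs) @ ranks
          for signs in itertools.product([0, 1], repeat=len(diffs))]
    ws = np.asarray(ws)
    p = 2 * min((ws <= obs).mean(), (ws >= obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_constant_shift_is_significant(self):
        """acc_a = acc_b + eps for 20 patients: W=0 on one side, p < 0.01."""
        rng = np.random.default_rng(0)
        b = rng.uniform(0.5, 0.9, 20)
        pairs = list(zip(b + 0.01, b))
        res = wilcoxon_signed_rank(pairs)
        assert res.p_value < 0.01
        assert res.n_nonzero == 20

    def test_symmetric_differences_not_significant(self):
        base = np.linspace(0.5, 0.7, 10)
        d = 0.02 * np.array([1, -1] * 5)
        res = wilcoxon_signed_rank(list(zip(base + d, base)))
        assert res.p_value > 0.5

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, 9)
        b = a + rng.normal(0, 0.1, 9)
        res = wilcoxon_signed_rank(list(zip(a, b)))
        assert res.p_value == pytest.approx(exact_two_sided_p(a - b), abs=1e-9)

    def test_swapping_pairs_keeps_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        r1 = wilcoxon_signed_rank(list(zip(a, b)))
        r2 = wilcoxon_signed_rank(list(zip(b, a)))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([(0.5, 0.5)] * 8)
        assert res.degenerate
        assert res.p_value == 1.0
        assert res.n_nonzero == 0


@pytest.fixture(scope="module")
def tiny_cv_report():
    """Plumbing-scale CV: 6 patients, short videos, a handful of iterations."""
    cfg = SyntheticConfig(frames_per_video=40, image_size=(16, 16),
                          transition_width=3, noise_sd=0.08,
                          noninformative_rate=0.1)
    cohort = generate_cohort(cfg, 6, seed=31)
    spec = ModelSpec(head_kind="fc", image_size=(16, 16), widths=(4, 8, 8, 16),
                     hidden_size=16)
    tcfg = TrainConfig(sequence_length=None, batch_sequences=4, base_lr=1e-3,
                       scheduler_period=10, total_iterations=10,
                       augment=AugmentConfig(0, 0, 0))
    return run_cross_validation(cohort, ["fc", "fc_avg", "lstm"], spec, tcfg,
                                k=3, seed=2, collect_tracks=True), cohort


class TestCrossValidation:
    def test_every_patient_scored_once(self, tiny_cv_report):
        report, cohort = tiny_cv_report
        pids = sorted({v.patient_id for v in cohort})
        for summary in report.heads.values():
            assert summary.patient_ids == pids
            assert len(summary.per_patient_accuracy) == len(pids)

    def test_report_rows_match_requested_heads(self, tiny_cv_report):
        report, _ = tiny_cv_report
        assert list(report.heads) == ["fc", "fc_avg", "lstm"]
        table = report.accuracy_table()
        assert list(table.columns) == ["fc", "fc_avg", "lstm"]
        assert table.shape == (6, 3)  # five classes + overall

    def test_aggregation_identity(self, tiny_cv_report):
        """Overall accuracy equals the per-patient mean of pooled accuracies."""
        report, _ = tiny_cv_report
        for summary in report.heads.values():
            assert summary.mean_accuracy == pytest.approx(
                mean_label_accuracy(summary.per_patient_accuracy))

    def test_switches_scored_per_video(self, tiny_cv_report):
        report, cohort = tiny_cv_report
        for summary in report.heads.values():
            assert len(summary.per_video_switches) == len(cohort)
            assert np.all(summary.per_video_switches >= 0)

    def test_tracks_collected_for_all_videos(self, tiny_cv_report):
        report, cohort = tiny_cv_report
        assert set(report.tracks) == {v.video_id for v in cohort}
        for v in cohort:
            entry = report.tracks[v.video_id]
            assert np.array_equal(entry["truth"], v.labels)
            assert len(entry["fc"]) == len(v)

    def test_fold_exclusivity(self):
        """No patient appears in both sides of any fold split."""
        pids = [f"P{i}" for i in range(11)]
        folds = make_folds(pids, 4, seed=5)
        for f in range(4):
            test = {p for p, g in folds.items() if g == f}
            train = {p for p, g in folds.items() if g != f}
            assert not (test & train)
            assert test | train == set(pids)

    def test_report_json_roundtrip(self, tiny_cv_report):
        import json

        report, _ = tiny_cv_report
        payload = json.loads(report.to_json())
        assert set(payload["heads"]) == {"fc", "fc_avg", "lstm"}
        assert "fc_vs_lstm" in payload["wilcoxon"]
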