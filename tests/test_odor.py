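"""Per odor-cell-pair response statistics and cohort classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from odorspike import (
    AnalysisWindows,
    EventTable,
    SpikeTrain,
    TrialAlignedCounts,
    compute_psth,
    epoch_trials,
    grand_average_psth,
    rank_biserial_paired,
    response_zscore,
    selectivity_index,
    tuning_profile,
)
from odorspike import test_pair_significance as pair_significance
from odorspike.odor import classify_cohort


def _counts(base, odor, **kw):
    return TrialAlignedCounts("c", "o", np.asarray(base), np.asarray(odor), **kw)


class TestEpochTrials:
    def test_forced_window_counts(self):
        ev = EventTable(
            pd.DataFrame(
                [{"odor_id": "a", "is_vehicle": True, "onset_s": 10.0, "offset_s": 12.0}]
            )
        )
        train = SpikeTrain("c", [9.5, 10.5, 11.5])
        (counts,) = epoch_trials(train, ev)
        assert counts.baseline_counts.tolist() == [1]
        assert counts.odor_counts.tolist() == [2]

    def test_empty_train_zero_counts(self, simple_events):
        out = epoch_trials(SpikeTrain("c", []), simple_events)
        assert all(
            c.baseline_counts.sum() == 0 and c.odor_counts.sum() == 0 for c in out
        )
        assert {c.odor_id for c in out} == {"odorA", "odorB", "oil"}

    def test_trial_with_baseline_before_start_dropped(self, caplog):
        ev = EventTable(
            pd.DataFrame(
                [
                    {"odor_id": "a", "is_vehicle": True, "onset_s": 2.0, "offset_s": 4.0},
                    {"odor_id": "a", "is_vehicle": True, "onset_s": 30.0, "offset_s": 32.0},
                ]
            )
        )
        with caplog.at_level("WARNING"):
            (counts,) = epoch_trials(SpikeTrain("c", [1.0, 31.0]), ev)
        assert counts.n_trials == 1
        assert "baseline precedes" in caplog.text

    def test_brute_force_recount_on_random_session(self, rng):
        onsets = 30.0 + 30.0 * np.arange(10)
        ev = EventTable(
            pd.DataFrame(
                [
                    {
                        "odor_id": "veh" if i == 0 else "a",
                        "is_vehicle": i == 0,
                        "onset_s": t,
                        "offset_s": t + 2,
                    }
                    for i, t in enumerate(onsets)
                ]
            )
        )
        times = np.unique(rng.uniform(0, 400, size=500))
        train = SpikeTrain("c", times)
        for counts in epoch_trials(train, ev):
            for j, onset in enumerate(ev.onsets_for(counts.odor_id)):
                assert counts.baseline_counts[j] == np.sum(
                    (times >= onset - 4) & (times < onset)
                )
                assert counts.odor_counts[j] == np.sum(
                    (times >= onset) & (times < onset + 4)
                )


class TestZScore:
    def test_identical_counts_zero(self):
        assert response_zscore(_counts([2, 3, 4], [2, 3, 4])) == 0.0

    def test_zero_sd_different_means_is_inf_sentinel(self):
        z = response_zscore(_counts([4, 4, 4, 4], [8, 8, 8, 8]))
        assert math.isinf(z) and z > 0
        z = response_zscore(_counts([4, 4, 4, 4], [1, 1, 1, 1]))
        assert math.isinf(z) and z < 0

    def test_constructed_arithmetic(self):
        # baseline rates {0.5, 1.0, 1.5} Hz: mean 1, sample SD 0.5; odor mean 2.5 Hz
        c = _counts([2, 4, 6], [10, 10, 10])
        assert response_zscore(c) == pytest.approx(3.0)

    def test_single_trial_undefined(self):
        assert math.isnan(response_zscore(_counts([1], [5])))

    def test_antisymmetric_under_swap(self, rng):
        base = rng.poisson(5, size=8)
        odor = rng.poisson(9, size=8)
        if np.std(base, ddof=1) == 0 or np.std(odor, ddof=1) == 0:
            pytest.skip("degenerate draw")
        z_fwd = response_zscore(_counts(base, odor))
        z_rev = response_zscore(_counts(odor, base))
        # swapping baseline and odor flips the sign (denominator changes scale)
        assert np.sign(z_fwd) == -np.sign(z_rev)


class TestRankBiserial:
    def test_all_positive_is_one(self):
        assert rank_biserial_paired(_counts([0] * 8, [1, 2, 3, 4, 5, 6, 7, 8])) == 1.0

    def test_antisymmetric_is_zero(self):
        assert rank_biserial_paired(_counts([2, 4], [4, 2])) == 0.0

    def test_all_zero_differences_degenerate_zero(self):
        assert rank_biserial_paired(_counts([3, 3], [3, 3])) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_signed_rank_enumeration(self, seed):
        """r equals (R+ - R-) / total computed from scratch on signed ranks."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            base = rng.poisson(4, size=n)
            odor = rng.poisson(5, size=n)
            d = (odor - base).astype(float)
            d = d[d != 0]
            if d.size == 0:
                expected = 0.0
            else:
                ranks = rankdata(np.abs(d))
                expected = (ranks[d > 0].sum() - ranks[d < 0].sum()) / ranks.sum()
            assert rank_biserial_paired(_counts(base, odor)) == pytest.approx(expected)

    def test_order_isomorphic_with_dominance(self, rng):
        """r = +1 exactly when every nonzero difference is positive."""
        for _ in range(50):
            base = rng.poisson(3, size=8)
            odor = rng.poisson(4, size=8)
            d = odor - base
            r = rank_biserial_paired(_counts(base, odor))
            if (d[d != 0] > 0).all() and (d != 0).any():
                assert r == 1.0
            elif (d != 0).any():
                assert r < 1.0


class TestPairSignificance:
    def test_identical_counts_null(self):
        res = pair_significance(_counts([2, 3, 4, 5], [2, 3, 4, 5]))
        assert res.p_wilcoxon == 1.0
        assert not res.significant and res.degenerate

    def test_eight_positive_trials_significant(self):
        res = pair_significance(_counts([1] * 8, [3, 4, 5, 6, 7, 8, 9, 10]))
        assert res.p_wilcoxon == pytest.approx(2 / 256)
        assert res.significant and res.r_rb == 1.0

    def test_flags_consistent_with_thresholds(self):
        w = AnalysisWindows(alpha_pair=0.05, sd_threshold=1.0)
        res = pair_significance(_counts([2, 4, 6], [10, 10, 10]), w)
        assert res.exceeds_sd == (res.z >= 1.0)
        assert res.significant == (res.p_wilcoxon < 0.05)

    def test_null_type_one_error_rate(self, rng):
        """Discrete-count conservatism keeps false positives at or below alpha."""
        n_sig = 0
        n_pairs = 1500
        for _ in range(n_pairs):
            base = rng.poisson(6, size=8)
            odor = rng.poisson(6, size=8)
            n_sig += pair_significance(_counts(base, odor)).significant
        assert n_sig / n_pairs <= 0.016


class TestSelectivity:
    def test_equal_rates_zero(self):
        assert selectivity_index([2.0, 2.0, 2.0]) == 0.0

    def test_boundary_one_when_min_zero(self):
        assert selectivity_index([0.0, 3.0]) == 1.0

    def test_formula(self):
        assert selectivity_index([2.0, 1.0, 0.5]) == pytest.approx(0.6)

    def test_undefined_cases(self):
        assert math.isnan(selectivity_index([1.5]))
        assert math.isnan(selectivity_index([0.0, 0.0]))

    def test_scale_invariance(self, rng):
        rates = rng.uniform(0.1, 8.0, size=6)
        assert selectivity_index(rates * 7.3) == pytest.approx(selectivity_index(rates))

    def test_tuning_profile_omits_vehicle(self):
        counts = [
            _counts([0] * 4, [8] * 4),
            TrialAlignedCounts("c", "veh", np.zeros(4, int), np.full(4, 99), is_vehicle=True),
            TrialAlignedCounts("c", "b", np.zeros(4, int), np.full(4, 4)),
        ]
        counts[0] = TrialAlignedCounts("c", "a", np.zeros(4, int), np.full(4, 8))
        prof = tuning_profile(counts)
        assert set(prof.odor_rates_hz) == {"a", "b"}
        assert prof.maxrate == pytest.approx(2.0)  # 8 spikes / 4 s
        assert prof.selectivity == pytest.approx((2 - 1) / (2 + 1))


class TestPsth:
    def test_homogeneous_train_flat(self):
        times = np.arange(0.05, 600, 0.1)  # exactly 10 Hz clock train
        psth = compute_psth(SpikeTrain("c", times), [100.0, 200.0, 300.0])
        np.testing.assert_allclose(psth.rate_hz, 10.0)

    def test_single_trial_sem_undefined(self):
        psth = compute_psth(SpikeTrain("c", [1.0, 2.0]), [50.0])
        assert psth.sem_hz is None

    def test_transient_peak_near_programmed_latency(self, rng):
        onsets = 100.0 * (1 + np.arange(20))
        times = []
        for onset in onsets:
            times.extend(onset + 0.5 + rng.uniform(0, 0.1, size=30))  # burst at +0.5 s
        times = np.unique(np.asarray(times))
        psth = compute_psth(SpikeTrain("c", times), onsets, bin_width_s=0.1)
        peak = psth.bin_centers_s[np.argmax(psth.rate_hz)]
        assert abs(peak - 0.55) <= 0.1

    def test_grand_average_identity_and_zero_sem(self):
        p = compute_psth(SpikeTrain("c", [1.0, 5.0, 9.0]), [4.0, 8.0])
        g1 = grand_average_psth([p])
        np.testing.assert_allclose(g1.rate_hz, p.rate_hz)
        g2 = grand_average_psth([p, p])
        np.testing.assert_allclose(g2.sem_hz, 0.0)
        assert grand_average_psth([]) is None


class TestClassifyCohort:
    @staticmethod
    def _tables():
        pairs = pd.DataFrame(
            {
                "cell_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
                "odor_id": ["a", "veh", "a", "veh", "a", "veh"],
                "is_vehicle": [False, True] * 3,
                "significant": [True, False, False, False, True, True],
                "exceeds_sd": [True, False, False, False, False, False],
                "z": [4.0, 0.0, 0.5, 0.1, 2.0, 3.5],
            }
        )
        cells = pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c3"],
                "region": ["DTT", "DTT", "AON"],
            }
        )
        return pairs, cells

    def test_hand_counted_proportions(self):
        pairs, cells = self._tables()
        summary = classify_cohort(pairs, cells).set_index("region")
        assert summary.loc["DTT", "n_pairs"] == 2  # vehicle excluded
        assert summary.loc["DTT", "n_significant_pairs"] == 1
        assert summary.loc["DTT", "prop_responsive_cells"] == pytest.approx(0.5)
        # c3's vehicle pair is significant but must not count
        assert summary.loc["AON", "n_significant_pairs"] == 1
        assert summary.loc["AON", "prop_significant_pairs"] == pytest.approx(1.0)

    def test_orphan_pair_rejected(self):
        pairs, cells = self._tables()
        pairs.loc[0, "cell_id"] = "ghost"
        with pytest.raises(Exception, match="ghost"):
            classify_cohort(pairs, cells)

    def test_no_significant_pairs_all_zero(self):
        pairs, cells = self._tables()
        pairs["significant"] = False
        summary = classify_cohort(pairs, cells)
        assert (summary["prop_responsive_cells"] == 0).all()
        assert (summary["n_significant_pairs"] == 0).all()
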