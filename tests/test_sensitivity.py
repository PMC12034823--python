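"""Trial selection, robust regression, permutation inference and FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from oddstream import (
    channel_sensitivity,
    fdr,
    permutation_pvalue,
    robust_slope,
    select_trials,
    synth_ei_table,
)


def _toy_table(tps, block_tone_index=None, channel="ch000"):
    n = len(tps)
    return pd.DataFrame(
        {
            "channel": channel,
            "event": np.arange(n),
            "block": 1,
            "block_tone_index": block_tone_index if block_tone_index is not None else 100 + np.arange(n),
            "identity": 1 + np.arange(n) % 8,
            "tp": tps,
            "ei_norm": np.ones(n),
            "included": True,
        }
    )


class TestSelectTrials:
    def test_tp_ceiling(self):
        table = _toy_table(np.round(np.arange(0.1, 0.95, 0.1), 1))
        kept = select_trials(table)
        assert kept["tp"].max() == pytest.approx(0.7)
        assert len(kept) == 7  # 0.8, 0.9 removed

    def test_all_rows_in_lead_in_removed(self):
        table = _toy_table([0.1, 0.2], block_tone_index=[3, 10])
        assert len(select_trials(table, burn_in=30)) == 0

    def test_no_exclusions_when_disabled(self):
        tps = [0.1, np.nan, 0.9]
        table = _toy_table(tps, block_tone_index=[0, 1, 2])
        kept = select_trials(table, burn_in=0, tp_max=1.0)
        assert len(kept) == 2  # only the undefined TP drops

    def test_burn_in_by_deviant_count(self):
        table = _toy_table(np.full(40, 0.2), block_tone_index=np.arange(40))
        kept = select_trials(table, burn_in=5, burn_in_unit="deviants")
        assert len(kept) == 35


class TestRobustSlope:
    def test_noiseless_line(self):
        x = np.linspace(0, 0.7, 50)
        slope, intercept = robust_slope(x, 1.0 - 1.05 * x)
        assert slope == pytest.approx(-1.05)
        assert intercept == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        slope, _ = robust_slope(np.linspace(0, 1, 20), np.full(20, 2.0))
        assert slope == pytest.approx(0.0)

    def test_zero_predictor_variance_raises(self):
        with pytest.raises(ValueError):
            robust_slope(np.full(20, 0.3), np.arange(20.0))

    def test_resists_gross_outliers_better_than_ols(self, rng):
        x = rng.uniform(0, 0.7, 300)
        y = 1.0 - 1.0 * x + rng.normal(0, 0.3, 300)
        y[:30] += 8.0  # 10% gross outliers
        robust, _ = robust_slope(x, y)
        ols = np.polyfit(x, y, 1)[0]
        assert abs(robust - (-1.0)) < abs(ols - (-1.0))

    def test_matches_statsmodels_rlm(self, rng):
        # independent implementation of the same estimator (bisquare IRLS)
        for _ in range(5):
            x = rng.uniform(0, 1, 200)
            y = 0.5 - 0.8 * x + rng.standard_t(3, 200) * 0.3
            slope, intercept = robust_slope(x, y)
            ref = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight()).fit()
            assert slope == pytest.approx(ref.params[1], abs=5e-3)
            assert intercept == pytest.approx(ref.params[0], abs=5e-3)


class TestPermutationPvalue:
    def test_strong_relation_hits_floor(self, rng):
        x = rng.uniform(0, 0.7, 200)
        y = 1.0 - 2.0 * x + rng.normal(0, 0.05, 200)
        p = permutation_pvalue(x, y, n_perm=200, rng=rng)
        assert p == pytest.approx(1 / 201)

    def test_reproducible_under_seed(self, rng):
        x = rng.uniform(0, 0.7, 100)
        y = rng.normal(0, 1, 100)
        p1 = permutation_pvalue(x, y, n_perm=200, rng=np.random.default_rng(5))
        p2 = permutation_pvalue(x, y, n_perm=200, rng=np.random.default_rng(5))
        assert p1 == p2

    def test_small_n_perm_warns(self, rng):
        x = rng.uniform(0, 1, 50)
        y = rng.normal(0, 1, 50)
        with pytest.warns(UserWarning):
            permutation_pvalue(x, y, n_perm=50, rng=rng)


def _brute_force_bh(p, q):
    """Step-up rule by direct evaluation."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestFDR:
    def test_all_ones_no_rejections(self):
        _, rej = fdr(np.ones(10))
        assert not rej.any()

    def test_worked_stepup_example(self):
        _, rej = fdr([0.01, 0.02, 0.04, 0.8], q=0.05)
        assert rej.sum() == 2  # largest k with p_(k) <= k/4 * 0.05 is k=2

    def test_single_pvalue_reduces_to_raw_threshold(self):
        _, rej = fdr([0.04], q=0.05)
        assert rej[0]

    def test_matches_brute_force_stepup(self, rng):
        for m in [1, 2, 5, 10, 20]:
            for _ in range(20):
                p = rng.uniform(0.001, 1, m)
                _, rej = fdr(p, q=0.05)
                assert np.array_equal(rej, _brute_force_bh(p, 0.05))

    def test_empty_input(self):
        q, rej = fdr([])
        assert q.size == 0 and rej.size == 0


class TestChannelSensitivity:
    def test_duplicated_channel_gets_identical_estimates(self, small_session):
        table, _ = synth_ei_table(small_session, beta=-1.0, sigma=0.3, seed=3)
        dup = table.copy()
        dup["channel"] = "ch001"
        both = pd.concat([table, dup], ignore_index=True)
        res = channel_sensitivity(both, n_perm=100, seed=0)
        a, b = res.iloc[0], res.iloc[1]
        assert a["slope"] == b["slope"]
        assert a["n_trials_used"] == b["n_trials_used"]

    def test_strong_coupling_detected(self, default_session):
        table, _ = synth_ei_table(default_session, beta=-1.0, sigma=0.3,
                                  n_channels=3, seed=5)
        res = channel_sensitivity(table, n_perm=200, seed=1)
        assert res["significant"].all()
        assert np.allclose(res["slope"], -1.0, atol=0.35)

    def test_too_few_trials_marks_unusable(self):
        table = _toy_table([0.1, 0.2, 0.3])
        res = channel_sensitivity(table, burn_in=0, n_perm=100, seed=0)
        assert not res["usable"].iloc[0]
        assert np.isnan(res["slope"].iloc[0])

    def test_join_mismatch_names_offending_events(self, small_session):
        table, _ = synth_ei_table(small_session, seed=0)
        tp = table[["event", "tp", "tp_defined"]].iloc[:-5]
        bare = table.drop(columns=["tp", "tp_defined"])
        with pytest.raises(ValueError, match="missing events"):
            channel_sensitivity(bare, tp_table=tp)

    def test_exclusion_tallies_account_for_all_trials(self, small_session):
        table, _ = synth_ei_table(small_session, seed=2)
        res = channel_sensitivity(table, n_perm=100, seed=0).iloc[0]
        total = (
            res["n_trials_used"]
            + res["n_excl_burn_in"]
            + res["n_excl_tp_high"]
            + res["n_excl_tp_undefined"]
            + res["n_excl_artifact"]
        )
        assert total == len(table)
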