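"""Amplitude binning, compression sizes, NCD and the EI table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oddstream import bin_signal, compressed_size, ncd
from oddstream.encoding import (
    NCD_EPSILON,
    encoded_information_table,
    ncd_result,
    normalize_ei,
)
from oddstream.hfa import EpochSet

WORKED_SIGNAL = [3.47, 2.14, 2.55, -0.18, 2.85, 1.05, 1.20, 2.94, 1.59]
WORKED_SYMBOLS = [12, 8, 9, 1, 10, 5, 5, 11, 6]


class TestBinSignal:
    def test_worked_nine_value_example(self):
        b = bin_signal(WORKED_SIGNAL, n_bins=12)
        assert b.symbols.tolist() == WORKED_SYMBOLS

    def test_worked_example_edges(self):
        b = bin_signal(WORKED_SIGNAL, n_bins=12)
        # interior edges are equally spaced between the extrema
        assert b.edges.size == 11
        assert b.edges[0] == pytest.approx(-0.18 + (3.47 + 0.18) / 12)
        assert np.allclose(np.diff(b.edges), (3.47 + 0.18) / 12)

    def test_extremes_map_to_first_and_last_bin(self):
        b = bin_signal([0.0, 0.5, 1.0], n_bins=8, lo=0.0, hi=1.0)
        assert b.symbols[0] == 1
        assert b.symbols[-1] == 8

    def test_constant_at_lo(self):
        b = bin_signal([2.0, 2.0], n_bins=4, lo=2.0, hi=3.0)
        assert (b.symbols == 1).all()

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError):
            bin_signal([1.0, 2.0], n_bins=4, lo=5.0, hi=5.0)

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            b = bin_signal([-1.0, 0.5, 2.0], n_bins=4, lo=0.0, hi=1.0)
        assert b.symbols[0] == 1 and b.symbols[-1] == 4

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50).filter(
        lambda v: max(v) > min(v)))
    def test_monotone_in_value(self, values):
        b = bin_signal(values, n_bins=16)
        order = np.argsort(values, kind="stable")
        assert (np.diff(b.symbols[order]) >= 0).all()


class TestCompression:
    def test_redundant_sequence_compresses_far_below_length(self):
        assert compressed_size(np.ones(400, dtype=int)) < 40

    def test_incompressible_sequence_near_entropy_bound(self, rng):
        # ~7 bits/symbol leaves little room below the 400-byte raw size
        u = rng.integers(1, 129, 400)
        assert 300 < compressed_size(u) < 420

    def test_deterministic(self, rng):
        u = rng.integers(1, 129, 400)
        assert compressed_size(u) == compressed_size(u)

    def test_symbols_above_byte_range_rejected(self):
        with pytest.raises(ValueError):
            compressed_size([1, 257])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compressed_size([])


class TestNCD:
    def test_self_distance_small(self, rng):
        for _ in range(5):
            x = rng.integers(1, 129, 400)
            assert ncd(x, x) <= 0.2

    def test_unrelated_signals_large(self, rng):
        const = np.full(400, 5)
        u = rng.integers(1, 129, 400)
        assert ncd(const, u) >= 0.8

    def test_bound_holds(self, rng):
        for _ in range(20):
            x = rng.integers(1, 129, rng.integers(10, 500))
            y = rng.integers(1, 129, rng.integers(10, 500))
            v = ncd(x, y)
            assert 0 <= v <= 1 + NCD_EPSILON

    def test_result_fields_consistent(self, rng):
        x = rng.integers(1, 129, 100)
        y = rng.integers(1, 129, 100)
        r = ncd_result(x, y)
        assert r.value == pytest.approx(
            (r.c_xy - min(r.c_x, r.c_y)) / max(r.c_x, r.c_y)
        )
        assert min(r.c_x, r.c_y, r.c_xy) > 0


def _epochs_with_perturbation(rng, amps, n_std=40, n_dev_per_amp=20, n_samp=400):
    """One channel per amplitude: standards share a template, deviants add
    white noise of the channel's amplitude."""
    template = np.sin(np.pi * np.arange(n_samp) / n_samp) * 3
    n_trials = n_std + n_dev_per_amp
    data = np.zeros((len(amps), n_trials, n_samp))
    cats, events = [], []
    for tr in range(n_trials):
        cats.append("standard" if tr < n_std else "deviant")
    for ch, a in enumerate(amps):
        for tr in range(n_trials):
            data[ch, tr] = template + rng.normal(0, 0.3, n_samp)
            if tr >= n_std:
                data[ch, tr] += rng.normal(0, a, n_samp)
    events = pd.DataFrame(
        {
            "event": np.arange(n_trials),
            "block": 1,
            "block_tone_index": np.arange(n_trials),
            "category": cats,
            "identity": [0] * n_std + [1 + i % 8 for i in range(n_dev_per_amp)],
        }
    )
    return EpochSet(data=data, sfreq=1000.0, t0_ms=0.0), events


class TestEncodedInformationTable:
    def test_identical_deviant_equals_self_distance(self):
        # a deviant trial equal to the mean standard scores ncd(x, x)
        n_samp = 200
        template = np.linspace(-1.0, 1.0, n_samp) ** 2
        data = np.tile(template, (1, 5, 1))
        events = pd.DataFrame(
            {
                "event": range(5),
                "block": 1,
                "block_tone_index": range(5),
                "category": ["standard"] * 4 + ["deviant"],
                "identity": [0, 0, 0, 0, 3],
            }
        )
        eps = EpochSet(data=data, sfreq=1000.0, t0_ms=0.0)
        table = encoded_information_table(eps, events)
        ref = bin_signal(template, 128)
        assert table["ei"].iloc[0] == pytest.approx(ncd(ref, ref))

    def test_mean_ei_monotone_in_perturbation_amplitude(self, rng):
        amps = [0.0, 0.5, 1.0, 2.0]
        eps, events = _epochs_with_perturbation(rng, amps)
        table = encoded_information_table(eps, events)
        means = [
            table.loc[table["channel"] == f"ch{ch:03d}", "ei"].mean()
            for ch in range(len(amps))
        ]
        assert np.all(np.diff(means) > 0)

    def test_channel_locality(self, rng):
        amps = [0.5, 1.5]
        eps, events = _epochs_with_perturbation(rng, amps)
        full = encoded_information_table(eps, events)
        solo = encoded_information_table(
            EpochSet(data=eps.data[:1], sfreq=eps.sfreq, t0_ms=0.0), events
        )
        a = full[full["channel"] == "ch000"]["ei"].to_numpy()
        assert np.allclose(a, solo["ei"].to_numpy())

    def test_rejected_deviants_excluded(self, rng):
        amps = [1.0]
        eps, events = _epochs_with_perturbation(rng, amps)
        eps.reject_mask[0, -1] = True
        table = encoded_information_table(eps, events)
        assert not table["included"].iloc[-1]
        assert np.isnan(table["ei"].iloc[-1])

    def test_channel_without_standards_skipped_with_warning(self, rng):
        amps = [1.0]
        eps, events = _epochs_with_perturbation(rng, amps)
        eps.reject_mask[0, :40] = True  # all standards gone
        with pytest.warns(UserWarning):
            table = encoded_information_table(eps, events)
        assert len(table) == 0


class TestNormalizeEI:
    @staticmethod
    def _table(eis, channel="ch000"):
        return pd.DataFrame(
            {
                "channel": channel,
                "event": np.arange(len(eis)),
                "ei": eis,
                "included": True,
            }
        )

    def test_equal_values_normalize_to_one(self):
        out = normalize_ei(self._table([0.4] * 6))
        assert np.allclose(out["ei_norm"], 1.0)

    def test_channel_mean_is_one(self, rng):
        out = normalize_ei(self._table(rng.uniform(0.2, 1.0, 50)))
        assert out["ei_norm"].mean() == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        eis = rng.uniform(0.2, 1.0, 30)
        a = normalize_ei(self._table(eis))["ei_norm"]
        b = normalize_ei(self._table(2 * eis))["ei_norm"]
        assert np.allclose(a, b)

    def test_subtractive_mode(self, rng):
        eis = rng.uniform(0.2, 1.0, 30)
        out = normalize_ei(self._table(eis), mode="subtract")
        assert out["ei_norm"].mean() == pytest.approx(0.0)

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError):
            normalize_ei(self._table([0.0, 0.0]))
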