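"""Compression-based encoded information of single-trial responses.

Kolmogorov complexity is uncomputable but is upper-bounded by the output
size of any lossless compressor.  The Normalized Compression Distance

    NCD(x, y) = [C(xy) - min(C(x), C(y))] / max(C(x), C(y))

with C(.) a compressed size and C(xy) the compressed concatenation, scores
how much information two signals share: near 0 for near-identical signals,
up to 1 + eps for unrelated ones, where eps absorbs compressor imperfection.

*Encoded information* (EI) applies this to neural data: each single-trial
deviant response is compared against the channel's mean response to
standard tones.  Signals are first discretized into equal-width amplitude
bins (128 by default) at the original sampling rate, serialized one byte
per sample, and compressed with a DEFLATE-family compressor at maximum
compression.  Larger EI means the deviant response carries more information
not present in the standard response.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BINS = 128
#: Allowance for compressor imperfection in the NCD upper bound.
NCD_EPSILON = 0.1
#: DEFLATE at maximum compression.
_COMPRESSION_LEVEL = 9


@dataclass
class BinnedSignal:
    """Integer-symbol representation of a signal after amplitude binning."""

    symbols: np.ndarray  # int64 in [1, n_bins]
    n_bins: int
    lo: float
    hi: float

    @property
    def edges(self) -> np.ndarray:
        """Interior bin edges (finite sentinels at +-inf are implicit)."""
        return self.lo + np.arange(1, self.n_bins) * (self.hi - self.lo) / self.n_bins


def bin_signal(x, n_bins: int = DEFAULT_BINS, lo: float | None = None, hi: float | None = None) -> BinnedSignal:
    """Discretize a signal into ``n_bins`` equal-width amplitude bins.

    Interior edges are ``e_k = lo + k (hi - lo) / n_bins`` for k = 1..B-1,
    with -inf / +inf sentinels at the ends; a value v maps to the bin k with
    ``e_{k-1} < v <= e_k``.  When lo/hi are omitted they default to the
    signal extrema.  Values outside a user-supplied range are clamped to the
    extreme bins with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bin an empty signal")
    if lo is None:
        lo = float(np.min(x))
    if hi is None:
        hi = float(np.max(x))
    if lo >= hi:
        raise ValueError(f"binning range degenerate: lo={lo} >= hi={hi}")
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn("signal values outside [lo, hi]; clamping to extreme bins")
    edges = lo + np.arange(1, n_bins) * (hi - lo) / n_bins
    # side="left": first edge >= v, so v == e_k lands in bin k (e_{k-1} < v <= e_k)
    symbols = np.searchsorted(edges, x, side="left") + 1
    return BinnedSignal(symbols=symbols.astype(np.int64), n_bins=n_bins, lo=lo, hi=hi)


def _symbol_bytes(symbols) -> bytes:
    if isinstance(symbols, BinnedSignal):
        symbols = symbols.symbols
    a = np.asarray(symbols)
    if a.size == 0:
        raise ValueError("empty symbol sequence")
    if a.min() < 1 or a.max() > 256:
        raise ValueError("symbols must lie in 1..256 for one-byte serialization")
    return (a - 1).astype(np.uint8).tobytes()


def compressed_size(symbols) -> int:
    """Compressed byte length of a symbol sequence (one byte per symbol,
    DEFLATE at maximum compression, full output incl. header).  Deterministic."""
    return len(zlib.compress(_symbol_bytes(symbols), _COMPRESSION_LEVEL))


@dataclass
class CompressionResult:
    """Sizes entering one NCD evaluation plus the resulting value."""

    c_x: int
    c_y: int
    c_xy: int
    value: float
    epsilon: float = NCD_EPSILON


def ncd_result(x_symbols, y_symbols) -> CompressionResult:
    """NCD between two symbol sequences, with the underlying sizes.

    Concatenation order is fixed (x then y) for determinism; with x the
    mean-standard reference and y the deviant trial in the EI pipeline.
    """
    bx = _symbol_bytes(x_symbols)
    by = _symbol_bytes(y_symbols)
    c_x = len(zlib.compress(bx, _COMPRESSION_LEVEL))
    c_y = len(zlib.compress(by, _COMPRESSION_LEVEL))
    c_xy = len(zlib.compress(bx + by, _COMPRESSION_LEVEL))
    value = (c_xy - min(c_x, c_y)) / max(c_x, c_y)
    return CompressionResult(c_x=c_x, c_y=c_y, c_xy=c_xy, value=value)


def ncd(x_symbols, y_symbols) -> float:
    """Normalized compression distance between two symbol sequences."""
    return ncd_result(x_symbols, y_symbols).value


#: Exclusion reason codes used in the EI table.
REASON_OK = ""
REASON_ARTIFACT = "artifact"


def encoded_information_table(hfa, events: pd.DataFrame, n_bins: int = DEFAULT_BINS) -> pd.DataFrame:
    """Encoded information of every deviant trial, per channel.

    Parameters
    ----------
    hfa : EpochSet
        Baseline-normalized HFA epochs restricted to the analysis window;
        the trial axis must align row-for-row with ``events``.
    events : DataFrame
        Event table with one row per trial (columns ``event``, ``block``,
        ``block_tone_index``, ``category``, ``identity``).

    For each channel the mean standard response is computed over retained
    standard trials; the binning range spans the global extrema of that mean
    response together with all the channel's retained deviant trials; EI of
    a deviant trial is the NCD between the binned mean standard and the
    binned trial.  Channels without retained standards are skipped with a
    warning.  Rejected deviant trials appear with ``included=False``.
    """
    data = hfa.data
    n_channels, n_trials, _ = data.shape
    if len(events) != n_trials:
        raise ValueError(
            f"events table has {len(events)} rows but epochs have {n_trials} trials"
        )
    reject = hfa.reject_mask
    if reject is None:
        reject = np.zeros((n_channels, n_trials), dtype=bool)
    names = hfa.channel_names or [f"ch{i:03d}" for i in range(n_channels)]

    is_std = (events["category"] == "standard").to_numpy()
    is_dev = (events["category"] == "deviant").to_numpy()
    rows = []
    for ch in range(n_channels):
        keep = ~reject[ch]
        std_idx = np.where(is_std & keep)[0]
        if std_idx.size == 0:
            warnings.warn(f"channel {names[ch]}: no retained standard trials; skipped")
            continue
        mean_std = data[ch, std_idx].mean(axis=0)
        dev_idx = np.where(is_dev)[0]
        kept_dev = dev_idx[keep[dev_idx]]
        if kept_dev.size:
            lo = min(mean_std.min(), data[ch, kept_dev].min())
            hi = max(mean_std.max(), data[ch, kept_dev].max())
        else:
            lo, hi = mean_std.min(), mean_std.max()
        ref = bin_signal(mean_std, n_bins=n_bins, lo=lo, hi=hi)
        for tr in dev_idx:
            included = bool(keep[tr])
            if included:
                trial = bin_signal(data[ch, tr], n_bins=n_bins, lo=lo, hi=hi)
                ei = ncd(ref, trial)
                reason = REASON_OK
            else:
                ei = float("nan")
                reason = REASON_ARTIFACT
            e = events.iloc[tr]
            rows.append(
                (
                    names[ch],
                    int(e["event"]),
                    int(e["block"]),
                    int(e["block_tone_index"]),
                    int(e["identity"]),
                    ei,
                    included,
                    reason,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "channel",
            "event",
            "block",
            "block_tone_index",
            "identity",
            "ei",
            "included",
            "reason",
        ],
    )


def normalize_ei(table: pd.DataFrame, mode: str = "divide") -> pd.DataFrame:
    """Normalize EI by the channel mean over included trials.

    ``divide`` (default): ei_norm = ei / mean(ei); the channel mean of
    ei_norm over included trials is then exactly 1.  ``subtract``:
    ei_norm = ei - mean(ei).  Corrects for per-channel differences in
    overall auditory responsiveness before the TP regression.
    """
    if mode not in ("divide", "subtract"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = table.copy()
    out["ei_norm"] = np.nan
    for ch, sub in table.groupby("channel"):
        inc = sub["included"]
        if not inc.any():
            continue
        mean = sub.loc[inc, "ei"].mean()
        if mode == "divide":
            if mean == 0:
                raise ValueError(f"channel {ch}: zero mean EI, cannot divide")
            out.loc[sub.index, "ei_norm"] = sub["ei"] / mean
        else:
            out.loc[sub.index, "ei_norm"] = sub["ei"] - mean
    return out
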