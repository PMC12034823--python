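"""High-frequency-activity (HFA) extraction pipeline for intracranial EEG.

Raw recordings are low-pass filtered at 180 Hz, notched at the line
frequency and its harmonics, resampled to 1000 Hz, optionally re-referenced
to a bipolar montage, segmented into 2000 ms epochs (750 ms pre-onset) and
demeaned.  Trials contaminated by residual artifacts are rejected by an
amplitude run-length rule and a power-spectral-density run-length rule.
HFA is then computed as the average of analytic-amplitude (Hilbert)
envelopes over eight 10-Hz-wide bands spanning 75-145 Hz, baseline
corrected per trial, normalized by the pooled baseline standard deviation
per channel, and restricted to the 0-400 ms post-onset analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

#: Default band centers: eight consecutive 10 Hz bands whose centers range
#: 75..145 Hz (each center +-5 Hz).
DEFAULT_BAND_CENTERS = tuple(range(75, 146, 10))
DEFAULT_BAND_HALFWIDTH = 5.0

#: Trial rejection reason codes.
REASONS = {0: "", 1: "edge", 2: "amplitude", 3: "psd"}
REASON_NONE, REASON_EDGE, REASON_AMPLITUDE, REASON_PSD = 0, 1, 2, 3


@dataclass
class EpochSet:
    """Channels x trials x samples array with epoch metadata.

    ``t0_ms`` is the epoch start relative to tone onset (default -750 ms).
    ``reject_mask`` marks (channel, trial) pairs excluded from all
    downstream statistics; ``reject_reason`` carries the integer code of
    :data:`REASONS`.
    """

    data: np.ndarray
    sfreq: float
    t0_ms: float = -750.0
    channel_names: list[str] | None = None
    reject_mask: np.ndarray | None = None
    reject_reason: np.ndarray | None = None

    def __post_init__(self):
        n_ch, n_tr, _ = self.data.shape
        if self.reject_mask is None:
            self.reject_mask = np.zeros((n_ch, n_tr), dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.zeros((n_ch, n_tr), dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def window_indices(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Sample indices with start_ms <= t < stop_ms (t relative to onset)."""
        t = self.times_ms()
        idx = np.where((t >= start_ms) & (t < stop_ms))[0]
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {stop_ms}) ms outside epoch")
        return idx


def preprocess_raw(
    data: np.ndarray,
    sfreq: float,
    lowpass_hz: float = 180.0,
    line_hz: float = 50.0,
    n_harmonics: int = 3,
    notch_halfwidth_hz: float = 2.0,
    resample_to: float = 1000.0,
) -> tuple[np.ndarray, float]:
    """Low-pass, line-noise removal and resampling of a continuous recording.

    ``data`` is channels x samples.  All filtering is zero-phase
    (forward-backward): an FIR low-pass at ``lowpass_hz`` and 4th-order
    Butterworth band-stops at the line frequency and its first
    ``n_harmonics - 1`` harmonics.  Returns the filtered data and the new
    sampling rate.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if sfreq <= 2 * lowpass_hz:
        raise ValueError(
            f"sampling rate {sfreq} Hz too low for a {lowpass_hz} Hz low-pass"
        )
    nyq = sfreq / 2.0
    # FIR low-pass, ~25 Hz transition band, Hamming window
    numtaps = 2 * int(round(1.65 * sfreq / 25.0)) + 1
    taps = sps.firwin(numtaps, lowpass_hz, fs=sfreq)
    out = sps.filtfilt(taps, [1.0], data, axis=-1)
    for h in range(1, n_harmonics + 1):
        f = line_hz * h
        if f + notch_halfwidth_hz >= nyq:
            break
        sos = sps.butter(
            2, [f - notch_halfwidth_hz, f + notch_halfwidth_hz], btype="bandstop", fs=sfreq, output="sos"
        )
        out = sps.sosfiltfilt(sos, out, axis=-1)
    if resample_to and resample_to != sfreq:
        frac = Fraction(resample_to / sfreq).limit_denominator(1000)
        out = sps.resample_poly(out, frac.numerator, frac.denominator, axis=-1)
        sfreq = resample_to
    return out, sfreq


def bipolar_reference(
    data: np.ndarray, names: list[str], pairs: list[tuple[str, str]]
) -> tuple[np.ndarray, list[str]]:
    """Re-reference to a bipolar montage: channel = anode - cathode.

    ``pairs`` lists (anode, cathode) electrode names; both must exist in
    ``names``.  Returns the derived channels and their "anode-cathode"
    labels.
    """
    index = {n: i for i, n in enumerate(names)}
    out = np.empty((len(pairs), data.shape[-1]), dtype=float)
    labels = []
    for k, (a, b) in enumerate(pairs):
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValueError(f"montage references unknown electrode {missing!r}")
        out[k] = data[index[a]] - data[index[b]]
        labels.append(f"{a}-{b}")
    return out, labels


def epoch(
    data: np.ndarray,
    sfreq: float,
    onsets_ms,
    t0_ms: float = -750.0,
    epoch_len_ms: float = 2000.0,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Segment a continuous recording into demeaned epochs around onsets.

    Events whose epoch would extend past the recording edge are flagged
    (reason ``edge``) on every channel rather than raising.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    n_len = int(round(epoch_len_ms * sfreq / 1000.0))
    epochs = np.zeros((n_ch, len(onsets_ms), n_len))
    mask = np.zeros((n_ch, len(onsets_ms)), dtype=bool)
    reason = np.zeros((n_ch, len(onsets_ms)), dtype=np.int8)
    for t, onset in enumerate(onsets_ms):
        start = int(round((onset + t0_ms) * sfreq / 1000.0))
        if start < 0 or start + n_len > n_samp:
            mask[:, t] = True
            reason[:, t] = REASON_EDGE
            continue
        seg = data[:, start : start + n_len]
        epochs[:, t, :] = seg - seg.mean(axis=-1, keepdims=True)
    return EpochSet(
        data=epochs,
        sfreq=sfreq,
        t0_ms=t0_ms,
        channel_names=channel_names,
        reject_mask=mask,
        reject_reason=reason,
    )


def _max_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a 2-D boolean array."""
    n, m = mask.shape
    padded = np.zeros((n, m + 2), dtype=np.int8)
    padded[:, 1:-1] = mask
    d = np.diff(padded, axis=1)
    out = np.zeros(n, dtype=int)
    for i in range(n):
        starts = np.flatnonzero(d[i] == 1)
        if starts.size:
            ends = np.flatnonzero(d[i] == -1)
            out[i] = int((ends - starts).max())
    return out


def reject_artifacts(
    epochs: EpochSet,
    amp_sd: float = 5.0,
    amp_run_ms: float = 25.0,
    psd_sd: float = 5.0,
    psd_run_hz: float = 6.0,
    psd_max_hz: float = 180.0,
) -> EpochSet:
    """Flag trials with residual artifacts.

    Amplitude rule: a trial is rejected when its absolute deviation from the
    channel mean (over all samples of all non-edge trials) exceeds
    ``amp_sd`` channel SDs for strictly longer than ``amp_run_ms``.
    PSD rule: per-trial periodogram power (1 Hz resolution, up to
    ``psd_max_hz``) exceeding the cross-trial mean by ``psd_sd`` SDs for
    strictly more than ``psd_run_hz`` consecutive Hz.  Reasons are recorded;
    previously flagged trials are preserved.
    """
    n_ch, n_tr, n_samp = epochs.data.shape
    if n_tr < 2:
        raise ValueError("artifact rejection needs at least 2 trials per channel")
    sfreq = epochs.sfreq
    mask = epochs.reject_mask.copy()
    reason = epochs.reject_reason.copy()
    amp_run_samples = amp_run_ms * sfreq / 1000.0

    nfft = int(round(sfreq))  # 1 Hz resolution
    for ch in range(n_ch):
        ok = ~mask[ch]
        if ok.sum() < 2:
            continue
        x = epochs.data[ch]
        mu = x[ok].mean()
        sd = x[ok].std()
        if sd > 0:
            dev = np.abs(x - mu) > amp_sd * sd
            runs = _max_run_lengths(dev)
            bad = ok & (runs > amp_run_samples)
            mask[ch, bad] = True
            reason[ch, bad] = REASON_AMPLITUDE

        ok = ~mask[ch]
        if ok.sum() < 2:
            continue
        # 1 Hz spectral resolution: Welch with 1-second segments
        freqs, pxx = sps.welch(x, fs=sfreq, nperseg=min(nfft, n_samp), axis=-1)
        sel = freqs <= psd_max_hz
        freqs, pxx = freqs[sel], pxx[:, sel]
        df = freqs[1] - freqs[0]
        p_mu = pxx[ok].mean(axis=0)
        p_sd = pxx[ok].std(axis=0)
        with np.errstate(invalid="ignore"):
            excess = (pxx - p_mu) > psd_sd * p_sd
        excess[:, p_sd == 0] = False
        runs_hz = _max_run_lengths(excess) * df
        bad = ok & (runs_hz > psd_run_hz)
        mask[ch, bad] = True
        reason[ch, bad] = REASON_PSD

    return replace(epochs, reject_mask=mask, reject_reason=reason)


def compute_hfa(
    epochs: EpochSet,
    band_centers=DEFAULT_BAND_CENTERS,
    band_halfwidth_hz: float = DEFAULT_BAND_HALFWIDTH,
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    analysis_ms: tuple[float, float] = (0.0, 400.0),
) -> EpochSet:
    """High-frequency-activity envelope per trial.

    Per band: zero-phase 4th-order Butterworth band-pass, Hilbert analytic
    amplitude, per-trial subtraction of the baseline mean.  Bands are then
    averaged; each channel is divided by the SD of baseline samples pooled
    over all its retained trials; the output is restricted to the analysis
    window.  Deterministic.
    """
    nyq = epochs.sfreq / 2.0
    top = max(band_centers) + band_halfwidth_hz
    if top >= nyq:
        raise ValueError(f"band edge {top} Hz at or above Nyquist {nyq} Hz")
    n_ch, n_tr, n_samp = epochs.data.shape
    base_idx = epochs.window_indices(*baseline_ms)
    n_fft = int(2 ** np.ceil(np.log2(n_samp)))

    acc = np.zeros_like(epochs.data)
    for c in band_centers:
        sos = sps.butter(
            2, [c - band_halfwidth_hz, c + band_halfwidth_hz], btype="bandpass", fs=epochs.sfreq, output="sos"
        )
        bp = sps.sosfiltfilt(sos, epochs.data, axis=-1)
        env = np.abs(sps.hilbert(bp, N=n_fft, axis=-1)[..., :n_samp])
        env -= env[..., base_idx].mean(axis=-1, keepdims=True)
        acc += env
    acc /= len(band_centers)

    keep = ~epochs.reject_mask
    for ch in range(n_ch):
        if not keep[ch].any():
            continue
        sd = acc[ch][keep[ch]][:, base_idx].std()
        if sd > 0:
            acc[ch] /= sd

    ana_idx = epochs.window_indices(*analysis_ms)
    return EpochSet(
        data=acc[..., ana_idx],
        sfreq=epochs.sfreq,
        t0_ms=analysis_ms[0],
        channel_names=epochs.channel_names,
        reject_mask=epochs.reject_mask.copy(),
        reject_reason=epochs.reject_reason.copy(),
    )
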