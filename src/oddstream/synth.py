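"""Synthetic recordings and trial tables with known ground truth.

Real intracranial patient data are confidential, so every downstream stage
is exercised on synthetic data whose generative parameters are known and
recoverable.  Two paths exist:

* ``synth_raw_session`` emits a continuous multichannel recording in which
  every tone evokes a stereotyped response (a half-sine amplitude envelope
  carrying a 110 Hz carrier, so that the response survives the 75-145 Hz
  pipeline) and every deviant additionally receives a white-noise
  perturbation whose amplitude grows as its transitional probability
  falls: amp = a0 + a1 * (1 - TP).  Additive noise makes low-TP responses
  less compressible, so encoded information rises when events get rarer —
  the coupling the analysis is designed to detect.
* ``synth_ei_table`` skips the signal level entirely and draws normalized
  encoded information directly from the regression model
  ei_norm = intercept + beta * TP + N(0, sigma^2), for fast calibration and
  parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import trial_tp_series
from .paradigm import StimulusSequence


@dataclass
class ChannelSpec:
    """Generative parameters of the raw-signal path.

    ``deviant_gain`` (a0) is the TP-independent perturbation amplitude and
    ``tp_coupling`` (a1) scales the (1 - TP) dependent part; both in units
    of the background ``noise_sd``.
    """

    n_channels: int = 4
    sfreq: float = 1000.0
    noise_sd: float = 1.0
    deviant_gain: float = 1.0
    tp_coupling: float = 1.0
    template_amplitude: float = 4.0
    carrier_hz: float = 110.0
    response_window_ms: tuple[float, float] = (0.0, 400.0)

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.deviant_gain < 0 or self.tp_coupling < 0:
            raise ValueError("deviant_gain and tp_coupling must be >= 0")

    def template(self) -> np.ndarray:
        """Evoked response: half-sine envelope on a carrier inside the HFA band."""
        n = int(round((self.response_window_ms[1] - self.response_window_ms[0]) * self.sfreq / 1000.0))
        t = np.arange(n) / self.sfreq
        envelope = np.sin(np.pi * np.arange(n) / n)
        return self.template_amplitude * envelope * np.sin(2 * np.pi * self.carrier_hz * t)


def synth_raw_session(
    sequence: StimulusSequence,
    spec: ChannelSpec,
    seed: int,
    tp_mode: str = "exclusive",
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Simulate a continuous multichannel recording for a stimulus sequence.

    Every tone adds the evoked template on all channels; every deviant adds
    white noise of amplitude ``a0 + a1 * (1 - TP)`` inside the response
    window, with TP from the ideal observer (``tp_mode``) and undefined TPs
    treated as 0 (maximal surprise).  Background Gaussian noise everywhere.
    Bit-identical under a fixed seed.

    Returns (data channels x samples, sfreq, per-deviant TP table).
    """
    if spec.response_window_ms[1] - spec.response_window_ms[0] > sequence.soa_ms:
        raise ValueError("response window longer than the SOA")
    rng = np.random.default_rng(seed)
    events = sequence.events
    sfreq = spec.sfreq
    n_samples = int(round((events["onset_ms"].iloc[-1] + 2500.0) * sfreq / 1000.0))
    data = rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, n_samples))

    template = spec.template()
    n_resp = template.size
    dev = events[events["category"] == "deviant"]
    tps = trial_tp_series(dev["identity"].to_numpy(), blocks=dev["block"].to_numpy(), mode=tp_mode)
    tp_by_event = dict(zip(dev["event"], tps["tp"]))

    w0 = int(round(spec.response_window_ms[0] * sfreq / 1000.0))
    for _, ev in events.iterrows():
        start = int(round(ev["onset_ms"] * sfreq / 1000.0)) + w0
        stop = min(start + n_resp, n_samples)
        if start >= n_samples:
            continue
        data[:, start:stop] += template[: stop - start]
        if ev["category"] == "deviant":
            tp = tp_by_event[ev["event"]]
            tp = 0.0 if np.isnan(tp) else float(tp)
            amp = spec.deviant_gain + spec.tp_coupling * (1.0 - tp)
            data[:, start:stop] += rng.normal(
                0.0, amp, size=(spec.n_channels, stop - start)
            )

    tp_table = dev[["event", "block", "block_tone_index", "identity"]].reset_index(drop=True)
    tp_table["tp"] = tps["tp"].to_numpy()
    tp_table["tp_defined"] = tps["tp_defined"].to_numpy()
    return data, sfreq, tp_table


def synth_ei_table(
    sequence: StimulusSequence,
    beta=-1.0,
    intercept: float = 1.0,
    sigma: float = 0.5,
    n_channels: int = 1,
    seed: int = 0,
    tp_mode: str = "exclusive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate normalized-EI tables straight from the regression model.

    TP values come from the ideal observer on the sequence's deviants; for
    each channel ei_norm = intercept + beta * TP + N(0, sigma^2).  ``beta``
    may be a scalar or one value per channel.  Returns (EI table, ground
    truth with the per-channel generating parameters).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    betas = np.broadcast_to(np.asarray(beta, dtype=float), (n_channels,))
    rng = np.random.default_rng(seed)
    dev = sequence.events[sequence.events["category"] == "deviant"]
    tps = trial_tp_series(dev["identity"].to_numpy(), blocks=dev["block"].to_numpy(), mode=tp_mode)
    base = dev[["event", "block", "block_tone_index", "identity"]].reset_index(drop=True)
    base["tp"] = tps["tp"].to_numpy()
    base["tp_defined"] = tps["tp_defined"].to_numpy()

    frames = []
    for ch in range(n_channels):
        sub = base.copy()
        sub.insert(0, "channel", f"ch{ch:03d}")
        noise = rng.normal(0.0, sigma, size=len(sub)) if sigma > 0 else 0.0
        sub["ei_norm"] = intercept + betas[ch] * sub["tp"] + noise
        sub["included"] = True
        frames.append(sub)
    table = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "channel": [f"ch{ch:03d}" for ch in range(n_channels)],
            "beta": betas,
            "intercept": intercept,
            "sigma": sigma,
        }
    )
    return table, truth
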