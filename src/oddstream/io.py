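"""Table and array readers/writers.

Tables are UTF-8 TSV with header rows (diff-able, BIDS-style for events);
array containers are compressed ``.npz`` with a JSON sidecar carrying the
sampling rate and channel names.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .hfa import EpochSet
from .paradigm import EVENT_COLUMNS, StimulusSequence

REQUIRED_EVENT_COLUMNS = [
    "onset_ms",
    "block",
    "category",
    "deviant_type",
    "version",
    "identity",
    "duration_ms",
]


def write_events(sequence: StimulusSequence, path) -> None:
    sequence.events.to_csv(path, sep="\t", index=False)


def read_events(path, soa_ms: float = 500.0, n_lead_in: int = 15) -> StimulusSequence:
    """Load a BIDS-style events TSV and validate the paradigm invariants.

    Missing required columns raise; invariant violations in user data are
    reported as warnings, one per issue, and the sequence is still returned.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing column(s): {missing}")
    if "event" not in df.columns:
        df.insert(0, "event", np.arange(len(df)))
    if "block_tone_index" not in df.columns:
        df["block_tone_index"] = df.groupby("block").cumcount()
    df = df[EVENT_COLUMNS]
    n_dev_per_block = df[df["category"] == "deviant"].groupby("block").size()
    n_sets = int(n_dev_per_block.iloc[0] // 5) if len(n_dev_per_block) else 0
    seq = StimulusSequence(
        events=df, soa_ms=soa_ms, n_lead_in=n_lead_in, n_sets_per_block=max(n_sets, 1)
    )
    for issue in seq.validate():
        warnings.warn(f"events file: {issue}")
    return seq


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_raw(path, data: np.ndarray, sfreq: float, channel_names=None) -> None:
    """Continuous recording -> compressed npz + JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, data=data)
    sidecar = {
        "sampling_rate_hz": sfreq,
        "channel_names": list(channel_names) if channel_names is not None else None,
        "shape": list(data.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_raw(path) -> tuple[np.ndarray, float, list[str] | None]:
    path = Path(path)
    with np.load(path) as z:
        data = z["data"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return data, float(sidecar["sampling_rate_hz"]), sidecar.get("channel_names")


def save_epochs(path, epochs: EpochSet) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        data=epochs.data,
        reject_mask=epochs.reject_mask,
        reject_reason=epochs.reject_reason,
    )
    sidecar = {
        "sampling_rate_hz": epochs.sfreq,
        "t0_ms": epochs.t0_ms,
        "channel_names": epochs.channel_names,
        "shape": list(epochs.data.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    with np.load(path) as z:
        data = z["data"]
        mask = z["reject_mask"]
        reason = z["reject_reason"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        sfreq=float(sidecar["sampling_rate_hz"]),
        t0_ms=float(sidecar["t0_ms"]),
        channel_names=sidecar.get("channel_names"),
        reject_mask=mask,
        reject_reason=reason,
    )
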