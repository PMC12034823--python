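"""Ideal-observer estimation of transitional probabilities between deviants.

The observer watches the stream of deviant identities (standards are
disregarded: transitions involving standards are static by design) and
incrementally maintains, after every deviant, the maximum-likelihood
transitional probability

    TP(Y | X) = frequency(X -> Y) / frequency(X),

where frequency(X -> Y) counts observed adjacent deviant pairs and
frequency(X) counts occurrences of identity X so far.  TPs therefore evolve
trial by trial as evidence accumulates.

Two per-trial conventions are supported.  In ``exclusive`` mode (default)
the TP attached to deviant trial t is computed from the state *before* the
transition into trial t is counted — the observer's prediction for the
event.  In ``inclusive`` mode the current transition is counted first.  The
first deviant of each block has no predecessor and an undefined (NaN) TP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import N_IDENTITIES


@dataclass
class TPState:
    """Running transition counts of the ideal observer.

    ``counts[x-1, y-1]`` is the number of observed x→y deviant transitions,
    ``occ[x-1]`` the number of occurrences of identity x, and ``last`` the
    most recent identity (or ``None`` at a sequence/block start).
    """

    n_identities: int = N_IDENTITIES
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    occ: np.ndarray = field(default=None)  # type: ignore[assignment]
    last: int | None = None

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((self.n_identities, self.n_identities), dtype=np.int64)
        if self.occ is None:
            self.occ = np.zeros(self.n_identities, dtype=np.int64)

    def reset_chain(self) -> None:
        """Forget the predecessor (block boundary); counts persist."""
        self.last = None


def update_state(state: TPState, identity: int) -> TPState:
    """Observe one deviant: bump its occurrence count and, if a predecessor
    exists, the corresponding transition count.  Mutates and returns state."""
    if not 1 <= identity <= state.n_identities:
        raise ValueError(f"identity {identity} out of range 1..{state.n_identities}")
    state.occ[identity - 1] += 1
    if state.last is not None:
        state.counts[state.last - 1, identity - 1] += 1
    state.last = identity
    return state


def tp_value(state: TPState, x: int, y: int) -> float:
    """TP(y | x) from the current state; NaN when x has never occurred."""
    if not (1 <= x <= state.n_identities and 1 <= y <= state.n_identities):
        raise ValueError("identities out of range")
    occ_x = state.occ[x - 1]
    if occ_x == 0:
        return float("nan")
    return state.counts[x - 1, y - 1] / occ_x


def tp_matrix(state: TPState) -> np.ndarray:
    """Full TP matrix; rows of never-seen identities are NaN."""
    occ = state.occ.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = state.counts / occ[:, None]
    m[occ == 0, :] = np.nan
    return m


def trial_tp_series(
    identities,
    blocks=None,
    mode: str = "exclusive",
    n_identities: int = N_IDENTITIES,
    reset_counts_between_blocks: bool = False,
) -> pd.DataFrame:
    """Per-deviant TP series over a stream of identities.

    Parameters
    ----------
    identities : sequence of int
        Deviant identities in presentation order (1..n_identities).
    blocks : sequence of int, optional
        Block label per deviant.  A block change resets the predecessor (no
        stimulus transition spans a recording gap); transition counts persist
        across blocks unless ``reset_counts_between_blocks`` is set.
    mode : {"exclusive", "inclusive"}
        Whether the TP of trial t is taken before or after counting the
        transition into trial t.

    Returns
    -------
    DataFrame with columns ``prev_identity`` (0 when none), ``identity``,
    ``tp`` and ``tp_defined``.
    """
    if mode not in ("exclusive", "inclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    identities = np.asarray(identities, dtype=int)
    if blocks is None:
        blocks = np.ones(len(identities), dtype=int)
    else:
        blocks = np.asarray(blocks, dtype=int)
        if len(blocks) != len(identities):
            raise ValueError("blocks and identities must have equal length")

    state = TPState(n_identities=n_identities)
    prev_block = None
    rows = []
    for ident, blk in zip(identities, blocks):
        if prev_block is not None and blk != prev_block:
            if reset_counts_between_blocks:
                state = TPState(n_identities=n_identities)
            else:
                state.reset_chain()
        prev_block = blk
        prev = state.last
        if prev is None:
            update_state(state, ident)
            rows.append((0, ident, float("nan"), False))
            continue
        if mode == "exclusive":
            tp = tp_value(state, prev, ident)
            update_state(state, ident)
        else:
            update_state(state, ident)
            tp = tp_value(state, prev, ident)
        rows.append((prev, ident, tp, not np.isnan(tp)))
    return pd.DataFrame(rows, columns=["prev_identity", "identity", "tp", "tp_defined"])


def observe_events(events: pd.DataFrame, mode: str = "exclusive", **kwargs) -> pd.DataFrame:
    """TP series for the deviants of an events table.

    Joins the per-deviant TP series back onto the event keys so downstream
    tables can merge on ``event``.
    """
    dev = events[events["category"] == "deviant"]
    series = trial_tp_series(
        dev["identity"].to_numpy(), blocks=dev["block"].to_numpy(), mode=mode, **kwargs
    )
    out = dev[["event", "block", "block_tone_index", "identity"]].reset_index(drop=True)
    out["prev_identity"] = series["prev_identity"]
    out["tp"] = series["tp"]
    out["tp_defined"] = series["tp_defined"]
    return out
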