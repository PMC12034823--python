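"""Optimum-1 multi-feature auditory oddball sequence generation.

The Optimum-1 paradigm interleaves a frequent standard tone with deviants
that differ from the standard along exactly one of five features: perceived
sound-source location, intensity, frequency, a silent gap in the middle of
the tone, or a shortened duration.  Location, intensity and frequency
deviants come in two equiprobable versions (left/right, high/low, high/low),
giving eight concrete deviant identities.

Each block opens with a short train of standards and then strictly
alternates standard and deviant tones at a fixed stimulus-onset asynchrony
(SOA).  Deviant types are scheduled in consecutive sets of five, each set a
uniform random permutation of the five types, with the constraint that the
same type never occurs twice in a row — including across set boundaries.
Hence every deviant type appears with probability exactly 0.1 among the
non-lead-in tones, while the transition structure between deviants drifts
randomly throughout the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five deviant feature dimensions.
DEVIANT_TYPES: tuple[str, ...] = ("location", "intensity", "frequency", "gap", "duration")

#: Admissible versions per deviant type.  Gap and duration deviants have a
#: single realization (version "none").
VERSIONS: dict[str, tuple[str, ...]] = {
    "location": ("left", "right"),
    "intensity": ("high", "low"),
    "frequency": ("high", "low"),
    "gap": ("none",),
    "duration": ("none",),
}

#: Frozen bijection between the eight concrete deviant stimuli and the
#: integer identity codes used to index transition matrices.  Standards
#: carry identity 0.
IDENTITY_CODES: dict[tuple[str, str], int] = {
    ("location", "left"): 1,
    ("location", "right"): 2,
    ("intensity", "high"): 3,
    ("intensity", "low"): 4,
    ("frequency", "high"): 5,
    ("frequency", "low"): 6,
    ("gap", "none"): 7,
    ("duration", "none"): 8,
}

#: Inverse of :data:`IDENTITY_CODES`.
CODE_TO_DEVIANT: dict[int, tuple[str, str]] = {v: k for k, v in IDENTITY_CODES.items()}

N_IDENTITIES = 8

STANDARD_DURATION_MS = 75.0
#: Duration deviants are shortened by one third (25 ms).
SHORT_DURATION_MS = 50.0

#: Canonical column order of the events table (BIDS-style TSV).
EVENT_COLUMNS = [
    "event",
    "onset_ms",
    "block",
    "block_tone_index",
    "category",
    "deviant_type",
    "version",
    "identity",
    "duration_ms",
]


def identity_code(deviant_type: str, version: str) -> int:
    """Return the frozen integer code (1..8) of a (type, version) deviant.

    Raises
    ------
    ValueError
        If the pair is not one of the eight admissible combinations.
    """
    key = (deviant_type, version)
    if key not in IDENTITY_CODES:
        raise ValueError(f"invalid deviant (type, version) pair: {key!r}")
    return IDENTITY_CODES[key]


@dataclass
class StimulusSequence:
    """An ordered table of timestamped tone events plus paradigm metadata.

    ``events`` holds one row per tone with the columns of
    :data:`EVENT_COLUMNS`; onsets are strictly increasing, blocks are
    separated recordings.
    """

    events: pd.DataFrame
    soa_ms: float = 500.0
    n_lead_in: int = 15
    n_sets_per_block: int = 60

    @property
    def n_blocks(self) -> int:
        if len(self.events) == 0:
            return 0
        return int(self.events["block"].max())

    def deviants(self) -> pd.DataFrame:
        """Rows of deviant tones only, in presentation order."""
        return self.events[self.events["category"] == "deviant"]

    def validate(self) -> list[str]:
        """Check the paradigm invariants; return a list of violation messages.

        Used when loading user-supplied event tables: violations are
        reported, not raised, since external data may legitimately deviate.
        """
        issues: list[str] = []
        ev = self.events
        if not ev["onset_ms"].is_monotonic_increasing:
            issues.append("onsets not strictly increasing")
        for blk, sub in ev.groupby("block"):
            onsets = sub["onset_ms"].to_numpy()
            if len(onsets) > 1 and not np.allclose(np.diff(onsets), self.soa_ms):
                issues.append(f"block {blk}: non-constant SOA")
            cats = sub["category"].to_numpy()
            lead = cats[: self.n_lead_in]
            if not np.all(lead == "standard"):
                issues.append(f"block {blk}: lead-in contains deviants")
            body = cats[self.n_lead_in :]
            expected = np.where(np.arange(len(body)) % 2 == 0, "standard", "deviant")
            if not np.array_equal(body, expected):
                issues.append(f"block {blk}: standard/deviant alternation broken")
            dev_types = sub.loc[sub["category"] == "deviant", "deviant_type"].to_numpy()
            if np.any(dev_types[1:] == dev_types[:-1]):
                issues.append(f"block {blk}: consecutive same-type deviants")
            n_dev = len(dev_types)
            if n_dev % 5 == 0:
                sets = dev_types.reshape(-1, 5)
                if not all(len(set(s)) == 5 for s in sets):
                    issues.append(f"block {blk}: a set of 5 deviants repeats a type")
            else:
                issues.append(f"block {blk}: deviant count {n_dev} not a multiple of 5")
        # identity consistency
        dev = ev[ev["category"] == "deviant"]
        for _, row in dev.iterrows():
            try:
                code = identity_code(row["deviant_type"], row["version"])
            except ValueError:
                issues.append(f"event {row['event']}: invalid (type, version)")
                continue
            if code != row["identity"]:
                issues.append(f"event {row['event']}: identity does not match (type, version)")
        if np.any(ev.loc[ev["category"] == "standard", "identity"] != 0):
            issues.append("standard with nonzero identity")
        return issues


def _draw_set(rng: np.random.Generator, prev_last_type: str | None) -> list[str]:
    # Rejection-resample a uniform permutation of the 5 types until its first
    # element differs from the previous set's last type.
    while True:
        perm = rng.permutation(len(DEVIANT_TYPES))
        first = DEVIANT_TYPES[perm[0]]
        if prev_last_type is None or first != prev_last_type:
            return [DEVIANT_TYPES[i] for i in perm]


def generate_block(
    seed: int | np.random.Generator,
    n_sets: int = 60,
    n_lead_in: int = 15,
    soa_ms: float = 500.0,
    prev_last_type: str | None = None,
    block: int = 1,
    onset0_ms: float = 0.0,
    event0: int = 0,
) -> StimulusSequence:
    """Generate one block: ``n_lead_in`` standards, then strict
    standard/deviant alternation with ``5 * n_sets`` deviants.

    ``prev_last_type`` optionally forbids the first deviant type (used when a
    caller wants the no-repeat constraint to continue from earlier material).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    types: list[str] = []
    last = prev_last_type
    for _ in range(n_sets):
        s = _draw_set(rng, last)
        types.extend(s)
        last = s[-1]
    versions = [
        VERSIONS[t][rng.integers(len(VERSIONS[t]))] if len(VERSIONS[t]) > 1 else "none"
        for t in types
    ]

    rows = []
    idx = 0

    def add(category: str, dtype: str, version: str):
        nonlocal idx
        identity = 0 if category == "standard" else identity_code(dtype, version)
        duration = STANDARD_DURATION_MS
        if dtype == "duration":
            duration = SHORT_DURATION_MS
        rows.append(
            (
                event0 + idx,
                onset0_ms + idx * soa_ms,
                block,
                idx,
                category,
                dtype,
                version,
                identity,
                duration,
            )
        )
        idx += 1

    for _ in range(n_lead_in):
        add("standard", "none", "none")
    for t, v in zip(types, versions):
        add("standard", "none", "none")
        add("deviant", t, v)

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return StimulusSequence(
        events=events, soa_ms=soa_ms, n_lead_in=n_lead_in, n_sets_per_block=n_sets
    )


def generate_session(
    seed: int,
    n_blocks: int = 6,
    n_sets_per_block: int = 60,
    n_lead_in: int = 15,
    soa_ms: float = 500.0,
    inter_block_gap_ms: float = 5000.0,
) -> StimulusSequence:
    """Generate a multi-block session.

    Blocks are independent recordings: the no-repeat constraint is not
    carried across block boundaries and a gap separates block onsets.  Child
    seeds per block are derived deterministically from ``seed``, so the same
    master seed always yields the same event table.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_blocks)
    frames = []
    onset0 = 0.0
    event0 = 0
    for b, child in enumerate(children, start=1):
        blk = generate_block(
            np.random.default_rng(child),
            n_sets=n_sets_per_block,
            n_lead_in=n_lead_in,
            soa_ms=soa_ms,
            prev_last_type=None,
            block=b,
            onset0_ms=onset0,
            event0=event0,
        )
        frames.append(blk.events)
        onset0 = blk.events["onset_ms"].iloc[-1] + soa_ms + inter_block_gap_ms
        event0 += len(blk.events)
    events = pd.concat(frames, ignore_index=True)
    return StimulusSequence(
        events=events, soa_ms=soa_ms, n_lead_in=n_lead_in, n_sets_per_block=n_sets_per_block
    )
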