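"""Pipeline configuration: defaults, YAML round-trip, content hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .hfa import DEFAULT_BAND_CENTERS


@dataclass
class PipelineConfig:
    """Every tunable of the analysis with its default.

    Defaults mirror the analysis conventions: 500 ms SOA, 15 lead-in
    standards and 60 sets of 5 deviants per block, 2000 ms epochs starting
    750 ms pre-onset, -100..0 ms baseline, 0..400 ms analysis window,
    eight 10-Hz HFA bands spanning 75-145 Hz, 128 amplitude bins, 30-trial
    burn-in, TP ceiling 0.7, 1000 permutations, FDR level 0.05.
    """

    seed: int = 0
    # paradigm
    n_blocks: int = 6
    n_sets_per_block: int = 60
    n_lead_in: int = 15
    soa_ms: float = 500.0
    # preprocessing / HFA
    line_hz: float = 50.0
    lowpass_hz: float = 180.0
    resample_to: float = 1000.0
    band_centers: tuple = DEFAULT_BAND_CENTERS
    band_halfwidth_hz: float = 5.0
    epoch_t0_ms: float = -750.0
    epoch_len_ms: float = 2000.0
    baseline_ms: tuple = (-100.0, 0.0)
    analysis_ms: tuple = (0.0, 400.0)
    # encoded information
    n_bins: int = 128
    normalization: str = "divide"
    # ideal observer
    tp_mode: str = "exclusive"
    # sensitivity
    burn_in: int = 30
    burn_in_unit: str = "tones"
    tp_max: float = 0.7
    n_perm: int = 1000
    alpha: float = 0.05
    min_trials: int = 10
    # synthetic data
    signal_path: str = "ei"  # "ei" (trial-level) or "raw" (full signal path)
    n_channels: int = 8
    beta: float = -1.0
    intercept: float = 1.0
    sigma: float = 0.5
    noise_sd: float = 1.0
    deviant_gain: float = 1.0
    tp_coupling: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("band_centers", "baseline_ms", "analysis_ms"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable content hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
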