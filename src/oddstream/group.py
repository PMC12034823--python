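"""ROI-level summaries and nonparametric group tests over channels.

Channels are grouped into anatomical regions of interest (ROIs) via a
channel map.  Per-ROI medians of encoded information or TP sensitivity are
compared with one-tailed Wilcoxon signed-rank tests against zero and
two-tailed pairwise Mann-Whitney-Wilcoxon tests between ROIs, with
Benjamini-Hochberg FDR across comparisons.  z-statistics use the normal
approximation with tie correction (the convention for reported effect
sizes); p-values use exact enumeration for small samples via scipy.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .sensitivity import fdr

#: Fixed ROI vocabulary (anatomical groupings typically engaged by auditory
#: processing and statistical learning).  Unknown labels are rejected.
ROI_VOCABULARY = (
    "superior_temporal_plane",
    "temporal_lateral",
    "temporal_basal",
    "insula_posterior",
    "insula_anterior",
    "inferior_frontal",
    "middle_frontal",
    "superior_frontal",
    "orbitofrontal",
    "acc",
    "pericentral",
    "parietal",
    "occipital",
    "hippocampus",
    "amygdala",
)

#: Threshold below which exact test enumeration is used instead of the
#: normal approximation.
EXACT_N = 25


def validate_channel_map(channel_map: pd.DataFrame) -> pd.DataFrame:
    """Check a channel->(subject, roi) map: unique channels, known ROIs."""
    required = {"channel", "subject", "roi"}
    missing = required - set(channel_map.columns)
    if missing:
        raise ValueError(f"channel map missing columns: {sorted(missing)}")
    dup = channel_map["channel"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate channels in map: {channel_map.loc[dup, 'channel'].tolist()}")
    unknown = set(channel_map["roi"]) - set(ROI_VOCABULARY)
    if unknown:
        raise ValueError(f"unknown ROI labels: {sorted(unknown)}")
    return channel_map


def roi_summary(
    values_by_channel: pd.DataFrame, channel_map: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Per-ROI median of a per-channel statistic.

    ``values_by_channel`` needs columns ``channel`` and ``value_col``.
    Empty ROIs are dropped with a warning.  Returns median, channel count
    and subject count per ROI.
    """
    validate_channel_map(channel_map)
    merged = values_by_channel.merge(channel_map, on="channel", how="inner")
    rows = []
    for roi in channel_map["roi"].unique():
        sub = merged[merged["roi"] == roi]
        if len(sub) == 0:
            warnings.warn(f"ROI {roi!r} has no channels with values; dropped")
            continue
        rows.append((roi, sub[value_col].median(), len(sub), sub["subject"].nunique()))
    return pd.DataFrame(rows, columns=["roi", "median", "n_channels", "n_subjects"])


def _signed_rank_z(values: np.ndarray) -> float:
    """Normal-approximation z for the Wilcoxon signed-rank statistic with
    tie correction; sign is positive for a positive median shift
    (independent of the tested tail)."""
    v = values[values != 0]
    n = v.size
    ranks = stats.rankdata(np.abs(v))
    w_plus = ranks[v > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie = (counts**3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie)
    return (w_plus - mu) / sigma if sigma > 0 else 0.0


def signed_rank_vs_zero(values, tail: str = "greater") -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank test of the median against zero.

    ``tail="greater"`` tests median > 0; ``"less"`` tests median < 0.
    Returns (p, z) with z from the tie-corrected normal approximation
    (p exact below n=25 via scipy's automatic method selection).
    """
    if tail not in ("greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    if np.all(v == 0):
        raise ValueError("all values are zero")
    method = "exact" if (v != 0).sum() <= EXACT_N and not _has_ties(v) else "approx"
    res = stats.wilcoxon(v, alternative=tail, method=method)
    return float(res.pvalue), float(_signed_rank_z(v))


def _has_ties(v: np.ndarray) -> bool:
    nz = np.abs(v[v != 0])
    return np.unique(nz).size < nz.size


def _mww_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected normal-approximation z for the Mann-Whitney U of a vs b."""
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie))
    return (u1 - mu) / sigma if sigma > 0 else 0.0


def pairwise_mww(groups: dict, q: float = 0.05) -> pd.DataFrame:
    """Two-tailed pairwise Mann-Whitney-Wilcoxon tests between groups.

    ``groups`` maps label -> 1-D array.  All pairs with both n >= 5 are
    tested; smaller pairs are skipped with a note column.  FDR is applied
    across the tested pairs.  z(A, B) = -z(B, A) by construction.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        va = np.asarray(groups[a], dtype=float)
        vb = np.asarray(groups[b], dtype=float)
        if va.size < 5 or vb.size < 5:
            rows.append((a, b, np.nan, np.nan, "skipped: group too small"))
            continue
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append((a, b, _mww_z(va, vb), float(res.pvalue), ""))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p", "note"])
    out["q"] = np.nan
    out["significant"] = False
    tested = out["p"].notna()
    if tested.any():
        q_adj, rej = fdr(out.loc[tested, "p"].to_numpy(), q=q)
        out.loc[tested, "q"] = q_adj
        out.loc[tested, "significant"] = rej
    return out


def significant_ratio(
    sensitivity_results: pd.DataFrame,
    channel_map: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Fractions of significant channels per (subject, ROI) with a bootstrap CI.

    Returns a dict with the per-cell table, the mean fraction across cells,
    and a seeded percentile bootstrap 95% CI of that mean.
    """
    validate_channel_map(channel_map)
    merged = sensitivity_results.merge(channel_map, on="channel", how="inner")
    cells = (
        merged.groupby(["subject", "roi"], sort=True)["significant"]
        .agg(fraction="mean", n_channels="size")
        .reset_index()
    )
    fracs = cells["fraction"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if fracs.size:
        boots = rng.choice(fracs, size=(n_boot, fracs.size), replace=True).mean(axis=1)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        mean = float(fracs.mean())
    else:
        mean, ci = float("nan"), (float("nan"), float("nan"))
    return {"cells": cells, "mean_fraction": mean, "ci95": ci}
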