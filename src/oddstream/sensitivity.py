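"""Channel-wise TP sensitivity: robust regression with permutation inference.

For each channel, normalized encoded information of deviant trials is
regressed on their ideal-observer transitional probabilities.  The robust
regression slope is the channel's *TP sensitivity*: negative values mean
rarer transitions (low TP) evoke responses carrying more information.

Trial selection follows the analysis conventions: the first trials of each
block are discarded (burn-in, while TP estimates are still unstable),
trials with TP above 0.7 are dropped (too sparse), undefined-TP trials are
dropped, and all eight deviant identities are pooled into one regressor.

Inference is by surrogate permutation: the TP regressor is shuffled
uniformly at random, destroying the tested association while preserving
both marginals; the two-sided p-value uses the add-one correction
p = (1 + #{|slope_null| >= |slope_obs|}) / (n_perm + 1), which cannot be
zero and is therefore valid input for Benjamini-Hochberg FDR control
across channels.

The robust estimator is iteratively reweighted least squares with Tukey
bisquare weights (c = 4.685) and a MAD residual scale, vectorized so that
the full stack of permutation refits runs as a few array operations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

TUKEY_C = 4.685
MAX_ITER = 50
COEF_TOL = 1e-8
_MAD_NORMAL = 0.6744897501960817  # Phi^{-1}(3/4): MAD -> sigma for a Gaussian


def select_trials(
    table: pd.DataFrame,
    burn_in: int = 30,
    tp_max: float = 0.7,
    burn_in_unit: str = "tones",
) -> pd.DataFrame:
    """Apply the trial-selection rules to an EI+TP table.

    Rows are removed when they fall within the first ``burn_in`` tone
    events of a block (``burn_in_unit="tones"``; ``"deviants"`` counts
    deviant trials instead), when tp > ``tp_max``, when tp is undefined, or
    when flagged as artifact (``included`` False).
    """
    if burn_in_unit not in ("tones", "deviants"):
        raise ValueError(f"unknown burn_in_unit {burn_in_unit!r}")
    df = table
    if "included" in df.columns:
        df = df[df["included"]]
    if burn_in > 0:
        if burn_in_unit == "tones":
            df = df[df["block_tone_index"] >= burn_in]
        else:
            cols = ["channel", "block"] if "channel" in df.columns else ["block"]
            rank = df.groupby(cols).cumcount()
            df = df[rank >= burn_in]
    df = df[df["tp"].notna()]
    df = df[df["tp"] <= tp_max]
    return df


def _irls_lines(x: np.ndarray, y: np.ndarray, c: float = TUKEY_C,
                max_iter: int = MAX_ITER, tol: float = COEF_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS line fits: row b of (slope, intercept) fits
    y[b] ~ x[b].  x and y are (B, n) and broadcast against each other."""
    x, y = np.broadcast_arrays(np.atleast_2d(x), np.atleast_2d(y))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    B, n = x.shape
    w = np.ones_like(x)

    def wls(w):
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swy = (w * y).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swxy = (w * x * y).sum(axis=1)
        det = sw * swxx - swx**2
        if np.any(det <= 0):
            raise ValueError("zero predictor variance (or all-zero weights)")
        slope = (sw * swxy - swx * swy) / det
        inter = (swy - slope * swx) / sw
        return slope, inter

    slope, inter = wls(w)
    for _ in range(max_iter):
        resid = y - inter[:, None] - slope[:, None] * x
        med = np.median(resid, axis=1, keepdims=True)
        scale = np.median(np.abs(resid - med), axis=1) / _MAD_NORMAL
        if np.all(scale < 1e-12):
            break  # (near-)perfect fit; weights undefined, keep current coefs
        scale = np.maximum(scale, 1e-12)
        u = resid / (c * scale[:, None])
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        # guard rows where everything was downweighted to zero
        dead = w.sum(axis=1) == 0
        if np.any(dead):
            w[dead] = 1.0
        new_slope, new_inter = wls(w)
        delta = np.maximum(np.abs(new_slope - slope), np.abs(new_inter - inter))
        ref = np.maximum(1.0, np.maximum(np.abs(new_slope), np.abs(new_inter)))
        slope, inter = new_slope, new_inter
        if np.all(delta < tol * ref):
            break
    return slope, inter


def robust_slope(tp_values, ei_norm_values, **kwargs) -> tuple[float, float]:
    """Robust (Tukey bisquare IRLS) line fit of EI on TP.

    Returns (slope, intercept).  Requires >= 3 points and nonzero predictor
    variance.
    """
    x = np.asarray(tp_values, dtype=float)
    y = np.asarray(ei_norm_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("tp and ei arrays must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero predictor variance")
    slope, inter = _irls_lines(x[None, :], y[None, :], **kwargs)
    return float(slope[0]), float(inter[0])


def permutation_pvalue(
    tp_values,
    ei_norm_values,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    return_slopes: bool = False,
):
    """Two-sided permutation p-value for the robust slope.

    Null slopes are obtained by refitting after permuting the TP regressor
    uniformly at random (EI order fixed).  Uses the add-one correction so
    that p in (0, 1].  Reproducible given a seeded generator.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: p-value resolution is coarse")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(tp_values, dtype=float)
    y = np.asarray(ei_norm_values, dtype=float)
    slope_obs, _ = robust_slope(x, y)
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    null_slopes, _ = _irls_lines(perms, y[None, :])
    p = (1 + np.sum(np.abs(null_slopes) >= np.abs(slope_obs))) / (n_perm + 1)
    if return_slopes:
        return float(p), float(slope_obs), null_slopes
    return float(p)


def fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, significance flags) at level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def channel_sensitivity(
    ei_table: pd.DataFrame,
    tp_table: pd.DataFrame | None = None,
    burn_in: int = 30,
    tp_max: float = 0.7,
    burn_in_unit: str = "tones",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_trials: int = 10,
) -> pd.DataFrame:
    """Per-channel TP sensitivity with permutation p-values and FDR.

    ``ei_table`` must carry ``channel``, ``event``, ``ei_norm`` (plus
    selection columns); TP columns may already be present or supplied via
    ``tp_table`` (joined on ``event``).  Each channel uses an independently
    reproducible random stream derived from (seed, channel index).  FDR is
    applied jointly across all usable channels.
    """
    df = ei_table
    if "tp" not in df.columns:
        if tp_table is None:
            raise ValueError("ei_table lacks tp columns and no tp_table given")
        missing = set(df["event"]) - set(tp_table["event"])
        if missing:
            raise ValueError(
                f"tp_table is missing events {sorted(missing)[:5]} (and possibly more)"
            )
        df = df.merge(tp_table[["event", "tp", "tp_defined"]], on="event", how="left")

    channels = sorted(df["channel"].unique())
    rows = []
    for idx, ch in enumerate(channels):
        sub = df[df["channel"] == ch]
        n_artifact = int((~sub["included"]).sum()) if "included" in sub.columns else 0
        inc = sub[sub["included"]] if "included" in sub.columns else sub
        n_undef = int(inc["tp"].isna().sum())
        kept = select_trials(sub, burn_in=burn_in, tp_max=tp_max, burn_in_unit=burn_in_unit)
        # tally: burn-in counted among included, defined-tp rows
        defined = inc[inc["tp"].notna()]
        n_tp_high = int((defined["tp"] > tp_max).sum())
        n_burn = len(defined) - n_tp_high - len(kept)
        n_used = len(kept)
        usable = n_used >= min_trials and np.var(kept["tp"].to_numpy()) > 0
        if usable:
            rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
            x = kept["tp"].to_numpy()
            y = kept["ei_norm"].to_numpy()
            slope, inter = robust_slope(x, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = permutation_pvalue(x, y, n_perm=n_perm, rng=rng)
        else:
            slope = inter = p = float("nan")
        rows.append((ch, slope, inter, p, n_used, n_burn, n_tp_high, n_undef, n_artifact, usable))

    out = pd.DataFrame(
        rows,
        columns=[
            "channel",
            "slope",
            "intercept",
            "p_perm",
            "n_trials_used",
            "n_excl_burn_in",
            "n_excl_tp_high",
            "n_excl_tp_undefined",
            "n_excl_artifact",
            "usable",
        ],
    )
    out["q_fdr"] = np.nan
    out["significant"] = False
    ok = out["usable"].to_numpy()
    if ok.any():
        q_adj, rej = fdr(out.loc[ok, "p_perm"].to_numpy(), q=alpha)
        out.loc[ok, "q_fdr"] = q_adj
        out.loc[ok, "significant"] = rej
    return out
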