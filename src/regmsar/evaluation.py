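"""Replication-study metrics: selection rates, bias and accuracy.

Selection of a coefficient uses one of three rules: the 95% credible
interval excluding zero, or the absolute posterior mean exceeding a
fixed threshold (0.1 or 0.15, strict inequality).  Power averages the
selection indicator over replications for truly nonzero coefficients;
the type-I error rate does the same for true zeros.  All metrics are
computed over converged replications only.

Admissible bands follow the replication-study convention: power in
[0.8, 1]; type-I error within 0.05 +/- 1.96 * sqrt(0.05*0.95/M), which
at M = 200 is approximately [0.02, 0.08].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicationSet",
    "SELECTION_RULES",
    "selection_decision",
    "power_and_type1",
    "accuracy_metrics",
    "admissible_bands",
    "metrics_table",
    "plot_rates",
    "EmptyReplicationError",
]

SELECTION_RULES = ("ci95", "thr_0.10", "thr_0.15")
POWER_BAND = (0.8, 1.0)


class EmptyReplicationError(RuntimeError):
    """Raised when no converged replications remain to average over."""


@dataclass
class ReplicationSet:
    """Per-replication posterior summaries of the slope vector.

    ``means``, ``lower`` and ``upper`` are (M_total, P); ``truth`` is the
    common generating slope vector; ``converged`` flags which
    replications enter the metrics.
    """

    means: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    truth: np.ndarray
    converged: np.ndarray

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.lower = np.atleast_2d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_2d(np.asarray(self.upper, dtype=float))
        self.truth = np.asarray(self.truth, dtype=float)
        self.converged = np.asarray(self.converged, dtype=bool)
        m, p = self.means.shape
        if self.lower.shape != (m, p) or self.upper.shape != (m, p):
            raise ValueError("means, lower and upper must share the shape (M, P)")
        if self.truth.shape != (p,):
            raise ValueError(f"truth must have length P={p}")
        if self.converged.shape != (m,):
            raise ValueError(f"converged must have length M={m}")

    @property
    def M(self) -> int:
        """Number of converged replications."""
        return int(np.sum(self.converged))

    def kept(self) -> "ReplicationSet":
        k = self.converged
        return ReplicationSet(self.means[k], self.lower[k], self.upper[k], self.truth, np.ones(int(k.sum()), dtype=bool))


def selection_decision(means, lower, upper, rule: str) -> np.ndarray:
    """Per-coefficient selection indicator under one rule.

    ``ci95`` selects when the interval (lower, upper) excludes zero;
    the thresholding rules select when |posterior mean| strictly exceeds
    the cutoff.
    """
    means = np.asarray(means, dtype=float)
    if rule == "ci95":
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        return (lower > 0.0) | (upper < 0.0)
    if rule == "thr_0.10":
        return np.abs(means) > 0.1
    if rule == "thr_0.15":
        return np.abs(means) > 0.15
    raise ValueError(f"unknown selection rule {rule!r}; expected one of {SELECTION_RULES}")


def power_and_type1(reps: ReplicationSet, rule: str) -> dict:
    """Power and type-I error under one rule, per coefficient and pooled."""
    kept = reps.kept()
    if kept.M == 0:
        raise EmptyReplicationError("no converged replications to evaluate")
    sel = selection_decision(kept.means, kept.lower, kept.upper, rule)
    nonzero = kept.truth != 0.0
    per_coef = sel.mean(axis=0)
    out = {
        "rule": rule,
        "M": kept.M,
        "per_coefficient": per_coef,
        "nonzero_mask": nonzero,
    }
    out["power"] = float(per_coef[nonzero].mean()) if nonzero.any() else float("nan")
    out["type1"] = float(per_coef[~nonzero].mean()) if (~nonzero).any() else float("nan")
    return out


def accuracy_metrics(reps: ReplicationSet) -> pd.DataFrame:
    """Bias, relative bias, absolute bias, RMSE and coverage per coefficient.

    The relative bias is undefined for true zeros and reported as NaN.
    """
    kept = reps.kept()
    if kept.M == 0:
        raise EmptyReplicationError("no converged replications to evaluate")
    err = kept.means - kept.truth[None, :]
    bias = err.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(kept.truth != 0.0, bias / kept.truth, np.nan)
    abs_bias = np.abs(err).mean(axis=0)
    rmse = np.sqrt((err**2).mean(axis=0))
    cover = (
        (kept.lower <= kept.truth[None, :]) & (kept.truth[None, :] <= kept.upper)
    ).mean(axis=0)
    return pd.DataFrame(
        {
            "coefficient": np.arange(1, kept.truth.size + 1),
            "truth": kept.truth,
            "mean_estimate": kept.means.mean(axis=0),
            "bias": bias,
            "relative_bias": rel,
            "absolute_bias": abs_bias,
            "rmse": rmse,
            "coverage95": cover,
        }
    )


def type1_band(M: int) -> tuple[float, float]:
    """Binomial band 0.05 +/- 1.96*sqrt(0.05*0.95/M) around the nominal level."""
    half = 1.96 * math.sqrt(0.05 * 0.95 / M)
    return (0.05 - half, 0.05 + half)


def admissible_bands(power: float | None, type1: float | None, M: int) -> dict:
    """Closed-interval band membership flags for a pair of rates."""
    lo, hi = type1_band(M)
    out = {"type1_band": (lo, hi), "power_band": POWER_BAND}
    if power is not None and not np.isnan(power):
        out["power_ok"] = bool(POWER_BAND[0] <= power <= POWER_BAND[1])
    if type1 is not None and not np.isnan(type1):
        out["type1_ok"] = bool(lo <= type1 <= hi)
    return out


def metrics_table(reps: ReplicationSet) -> pd.DataFrame:
    """Combined selection-rate table over all three rules with band flags."""
    rows = []
    for rule in SELECTION_RULES:
        r = power_and_type1(reps, rule)
        bands = admissible_bands(r["power"], r["type1"], r["M"])
        rows.append(
            {
                "rule": rule,
                "M": r["M"],
                "power": r["power"],
                "type1": r["type1"],
                "power_in_band": bands.get("power_ok"),
                "type1_in_band": bands.get("type1_ok"),
            }
        )
    return pd.DataFrame(rows)


def plot_rates(tables: dict, metric: str = "power", ax=None):
    """Bar panel of a selection metric across labelled conditions.

    ``tables`` maps a condition label to a ``metrics_table`` frame; the
    admissible band is shaded.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    labels = list(tables)
    width = 0.8 / len(SELECTION_RULES)
    xs = np.arange(len(labels))
    for j, rule in enumerate(SELECTION_RULES):
        vals = [float(tables[k].set_index("rule").loc[rule, metric]) for k in labels]
        ax.bar(xs + j * width, vals, width=width, label=rule)
    if metric == "power":
        ax.axhspan(*POWER_BAND, color="0.85", zorder=0)
    else:
        m = int(tables[labels[0]]["M"].iloc[0])
        ax.axhspan(*type1_band(m), color="0.85", zorder=0)
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    return ax
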