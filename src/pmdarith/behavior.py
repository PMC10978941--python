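"""Behavioural statistics: selection rates, tuning fits, and shared tests.

Covers the behavioural battery of the study: selection-rate matrices over
chosen numerosity, exact binomial tests against chance, Gaussian tuning fits
whose standard deviation indexes decision noise, the numerical size-effect
regression (sigma growing with target numerosity), the exact McNemar test for
paired consistency, and the reaction-time congruency contrast. The exact
upper-tail binomial test defined here is also the series-level summary test
used by the ROC and decoding stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import task as T

NUMEROSITIES = np.arange(7)


@dataclass
class SelectionMatrix:
    """Row-normalised choice proportions over chosen numerosity 0-6."""

    proportions: pd.DataFrame  # index = condition, columns = 0..6
    counts: pd.Series          # trials per condition row

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1).to_numpy()
        ok = self.counts.to_numpy() > 0
        if not np.allclose(sums[ok], 1.0, atol=1e-12):
            raise ValueError("selection-rate rows must sum to 1")


@dataclass
class GaussianFitResult:
    """Per-condition Gaussian tuning parameters (sigma = decision noise)."""

    table: pd.DataFrame  # condition, mean, sigma, r2, converged


def selection_rates(trials: pd.DataFrame, by: str = "target") -> SelectionMatrix:
    """Choice proportion matrix, rows indexed by condition.

    ``by='target'`` groups numerical-task trials by target numerosity (the
    headline behavioural panel); ``by='pair'`` keeps every (target, preop)
    pair; ``by='instruction'`` groups instructed trials by
    (instruction, preop).
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    if by == "target":
        key = trials["target_numerosity"].astype(int)
    elif by == "pair":
        key = [trials["target_numerosity"].astype(int),
               trials["preoperational_numerosity"].astype(int)]
    elif by == "instruction":
        key = [trials["instruction"],
               trials["preoperational_numerosity"].astype(int)]
    else:
        raise ValueError(f"unknown grouping {by!r}")
    tab = pd.crosstab(key, trials["chosen_numerosity"].astype(int))
    tab = tab.reindex(columns=NUMEROSITIES, fill_value=0)
    counts = tab.sum(axis=1)
    props = tab.div(counts.where(counts > 0, 1), axis=0)
    return SelectionMatrix(proportions=props, counts=counts)


def binomial_tail_test(successes: int, n: int, p_chance: float) -> float:
    """Exact one-sided upper-tail binomial p-value, P(X >= successes)."""
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    if not 0 < p_chance < 1:
        raise ValueError("need 0 < p_chance < 1")
    return float(stats.binom.sf(successes - 1, n, p_chance))


def performance_vs_chance(trials: pd.DataFrame, chance: float = 0.25,
                          by: str = "target") -> pd.DataFrame:
    """Per-condition correct counts with upper-tail binomial p vs chance."""
    if by == "target":
        key = trials["target_numerosity"].astype(int)
    else:
        key = trials["instruction"]
    grp = trials.groupby(key)["correct"]
    out = grp.agg(n="count", successes="sum").reset_index()
    out["fraction"] = out["successes"] / out["n"]
    out["p"] = [binomial_tail_test(int(s), int(n), chance)
                for s, n in zip(out["successes"], out["n"])]
    return out


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_tuning(matrix: SelectionMatrix) -> GaussianFitResult:
    """Least-squares Gaussian fit (free amplitude, mean, sigma) per row."""
    rows = []
    for cond, row in matrix.proportions.iterrows():
        y = row.to_numpy(float)
        if (y > 0).sum() < 3 and y.max() < 1.0:
            rows.append((cond, np.nan, np.nan, np.nan, False))
            continue
        p0 = (float(y.max()), float(np.argmax(y)), 1.0)
        try:
            popt, _ = optimize.curve_fit(
                _gauss, NUMEROSITIES.astype(float), y, p0=p0,
                bounds=([0.0, -1.0, 1e-3], [2.0, 7.0, 10.0]), maxfev=5000,
            )
            resid = y - _gauss(NUMEROSITIES, *popt)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan
            rows.append((cond, popt[1], popt[2], r2, True))
        except RuntimeError:
            rows.append((cond, np.nan, np.nan, np.nan, False))
    return GaussianFitResult(
        pd.DataFrame(rows, columns=["condition", "mean", "sigma", "r2", "converged"])
    )


def size_effect_regression(fit: GaussianFitResult,
                           x: np.ndarray | None = None) -> dict:
    """OLS of tuning sigma on target numerosity (the numerical size effect)."""
    tab = fit.table[fit.table["converged"]]
    xs = np.asarray(x if x is not None else tab["condition"], dtype=float)
    ys = tab["sigma"].to_numpy(float)
    if len(xs) < 3:
        raise ValueError("need at least 3 fitted conditions")
    if np.allclose(xs, xs[0]):
        raise ValueError("degenerate regressor: all conditions equal")
    if np.allclose(ys, ys[0]):
        return {"slope": 0.0, "intercept": float(ys[0]), "r2": 0.0, "p": 1.0}
    res = stats.linregress(xs, ys)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue)}


def mcnemar_consistency(table: np.ndarray | tuple[int, int]) -> float:
    """Exact two-sided McNemar test on paired binary outcomes.

    Accepts a 2x2 contingency table (discordant cells at [0,1] and [1,0]) or
    the discordant pair counts directly. Zero discordant pairs -> p = 1.
    """
    arr = np.asarray(table)
    if arr.shape == (2, 2):
        b, c = int(arr[0, 1]), int(arr[1, 0])
    elif arr.shape == (2,):
        b, c = int(arr[0]), int(arr[1])
    else:
        raise ValueError("expected a 2x2 table or (b, c) discordant counts")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def rt_congruency_contrast(trials: pd.DataFrame, min_per_cell: int = 5) -> pd.DataFrame:
    """Median RT difference (addition - subtraction) per hand, Mann-Whitney p.

    A negative difference for the right hand and positive for the left hand
    is the SNARC-like congruency signature. Hands with fewer than
    ``min_per_cell`` trials in either operation are flagged (p = NaN).
    """
    df = trials[trials.get("label_valid", pd.Series(True, index=trials.index))]
    rows = []
    for hand in (T.LEFT, T.RIGHT):
        add = df.loc[(df["hand"] == hand) & (df["arithmetic"] == T.ADDITION),
                     "reaction_time_ms"].to_numpy()
        sub = df.loc[(df["hand"] == hand) & (df["arithmetic"] == T.SUBTRACTION),
                     "reaction_time_ms"].to_numpy()
        if min(len(add), len(sub)) < min_per_cell:
            rows.append((hand, len(add), len(sub), np.nan, np.nan))
            continue
        diff = float(np.median(add) - np.median(sub))
        if np.array_equal(np.sort(add), np.sort(sub)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(add, sub, alternative="two-sided").pvalue)
        rows.append((hand, len(add), len(sub), diff, p))
    return pd.DataFrame(rows, columns=["hand", "n_addition", "n_subtraction",
                                       "median_rt_diff_ms", "p"])
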