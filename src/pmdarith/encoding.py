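"""Per-cell binwise factor regression, coding history and cell categories.

Each cell's firing rate in every 100-ms bin of the concern period is
regressed on four dummy-coded task factors,

    rate = b0 + b1*arithmetic + b2*hand + b3*step + b4*stimulus_type,

with a factor deemed significant in a bin when its coefficient's two-sided
t-test p-value is below 0.01. A cell's *coding history* is the cumulative
set of factors (arithmetic, hand, step; never stimulus type) significant in
at least one bin up to the end of each analysis period (preoperational,
delay 2, operation). Cells whose preoperational history contains arithmetic
are arithmetic-related; to exclude magnitude-comparison correlates, a second
regression on instructed-task activity (rate = b0 + b5*instruction, bins
0-700 ms after instruction onset) must also reach significance in at least
one bin for the cell to count as arithmetic-*selective*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import task as T
from .population import BinnedPopulation

HISTORY_FACTORS = ("arithmetic", "hand", "step")
ALPHA_DEFAULT = 0.01


def bin_spike_counts(
    spike_times: list[list[np.ndarray]],
    trials: pd.DataFrame,
    timeline: T.EventTimeline = T.DEFAULT_TIMELINE,
) -> BinnedPopulation:
    """Bin raw spike times into the 24 concern-period windows.

    ``spike_times[cell][trial]`` holds spike times in ms on the trial clock
    (fixation onset = 0). Bins are half-open [t, t+100): bins 0-16 tile
    preoperational onset to +1700 ms and bins 17-23 tile Go to Go+700 ms.
    Trials missing event times are dropped with a warning.
    """
    need = ["t_preop_on", "t_go"]
    ok = trials[need].notna().all(axis=1)
    if not ok.all():
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d trials without alignment events", int((~ok).sum()))
    trials = trials.loc[ok].reset_index(drop=True)
    keep_idx = np.flatnonzero(ok.to_numpy())
    bw = timeline.bin_width_ms
    n_cells = len(spike_times)
    counts = np.zeros((n_cells, len(trials), timeline.n_bins), dtype=np.int32)
    for t_new, t_orig in enumerate(keep_idx):
        preop = trials.at[t_new, "t_preop_on"]
        go = trials.at[t_new, "t_go"]
        edges = np.concatenate([preop + bw * np.arange(18),
                                go + bw * np.arange(1, 8)])
        for c in range(n_cells):
            st = np.sort(np.asarray(spike_times[c][t_orig], dtype=float))
            counts[c, t_new] = np.diff(np.searchsorted(st, edges, side="left"))
    return BinnedPopulation(counts, trials, bin_width_ms=bw)


@dataclass
class BinRegressionResult:
    """OLS results per cell x bin: coefficients, p-values, significance flags."""

    coef: np.ndarray        # cells x bins x n_regressors (incl. intercept)
    pvals: np.ndarray       # cells x bins x n_factors (NaN = unestimable)
    flags: np.ndarray       # cells x bins x n_factors, pvals < alpha
    factors: tuple[str, ...]
    alpha: float
    cell_ids: np.ndarray
    bins: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (cell, bin, factor, coef, p, significant)."""
        rows = []
        for ci, cell in enumerate(self.cell_ids):
            for bi, b in enumerate(self.bins):
                for fi, f in enumerate(self.factors):
                    rows.append((cell, b, f, self.coef[ci, bi, fi + 1],
                                 self.pvals[ci, bi, fi], bool(self.flags[ci, bi, fi])))
        return pd.DataFrame(rows, columns=["cell_id", "bin", "factor",
                                           "coef", "p", "significant"])


def _dummy(series: pd.Series, positive) -> np.ndarray:
    return (series == positive).to_numpy(float)


def _ols_tp(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS of every column of Y on X; returns (beta, pvals).

    beta is (k, m); pvals are two-sided t-test p-values per coefficient.
    """
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, pvals


def binwise_regression(
    pop: BinnedPopulation,
    bins: np.ndarray | range | None = None,
    alpha: float = ALPHA_DEFAULT,
    min_per_level: int = 5,
) -> BinRegressionResult:
    """Four-factor dummy regression per cell per 100-ms bin.

    Dummy coding: addition / right hand / 1 step / standard stimulus = 1, the
    other level 0 (the significance pattern is invariant to the assignment).
    Factors with fewer than ``min_per_level`` trials on either level are
    unestimable and reported as NaN rather than imputed.
    """
    pop = pop.subset_valid()
    tr = pop.trials
    bins = np.asarray(bins if bins is not None else range(pop.n_bins))
    cols = {
        "arithmetic": _dummy(tr["arithmetic"], T.ADDITION),
        "hand": _dummy(tr["hand"], T.RIGHT),
        "step": (tr["step"].astype(float) == 1).to_numpy(float),
        "stimulus_type": _dummy(tr["stimulus_type"], T.STANDARD),
    }
    usable = [f for f, d in cols.items()
              if min(int(d.sum()), int(len(d) - d.sum())) >= min_per_level]
    X = np.column_stack([np.ones(len(tr))] + [cols[f] for f in usable])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded design: factor dummies are collinear")

    rates = pop.rates[:, :, bins]  # cells x trials x bins
    n_cells, _, n_bins = rates.shape
    Y = rates.transpose(1, 0, 2).reshape(len(tr), n_cells * n_bins)
    beta, pv = _ols_tp(X, Y)

    factors = tuple(cols)
    coef = np.zeros((n_cells, n_bins, len(factors) + 1))
    pvals = np.full((n_cells, n_bins, len(factors)), np.nan)
    coef[:, :, 0] = beta[0].reshape(n_cells, n_bins)
    for fi, f in enumerate(factors):
        if f in usable:
            j = 1 + usable.index(f)
            coef[:, :, fi + 1] = beta[j].reshape(n_cells, n_bins)
            pvals[:, :, fi] = pv[j].reshape(n_cells, n_bins)
    flags = np.where(np.isnan(pvals), False, pvals < alpha)
    return BinRegressionResult(coef, pvals, flags.astype(bool), factors, alpha,
                               pop.cell_ids, bins)


def regress_instruction(
    pop: BinnedPopulation,
    bins: np.ndarray | range = range(7),
    alpha: float = ALPHA_DEFAULT,
    min_per_level: int = 5,
) -> BinRegressionResult:
    """Instructed-task single-factor regression (rate = b0 + b5*instruction)."""
    tr = pop.trials
    keep = tr["instruction"].isin([T.PLUS, T.MINUS]).to_numpy()
    tr = tr.loc[keep]
    bins = np.asarray(bins)
    d = _dummy(tr["instruction"], T.PLUS)
    n_cells = pop.n_cells
    n_bins = len(bins)
    if min(int(d.sum()), int(len(d) - d.sum())) < min_per_level:
        pvals = np.full((n_cells, n_bins, 1), np.nan)
        coef = np.zeros((n_cells, n_bins, 2))
    else:
        X = np.column_stack([np.ones(len(tr)), d])
        rates = pop.rates[:, keep, :][:, :, bins]
        Y = rates.transpose(1, 0, 2).reshape(len(tr), n_cells * n_bins)
        beta, pv = _ols_tp(X, Y)
        coef = np.stack([beta[0].reshape(n_cells, n_bins),
                         beta[1].reshape(n_cells, n_bins)], axis=-1)
        pvals = pv[1].reshape(n_cells, n_bins, 1)
    flags = np.where(np.isnan(pvals), False, pvals < alpha)
    return BinRegressionResult(coef, pvals, flags.astype(bool), ("instruction",),
                               alpha, pop.cell_ids, bins)


@dataclass
class CodingHistory:
    """Per-cell factor sets per analysis period, and their cumulative union."""

    cell_ids: np.ndarray
    periods: tuple[str, ...]
    per_period: np.ndarray   # cells x periods x 3 factors (bool)
    cumulative: np.ndarray   # cells x periods x 3 factors (bool, monotone)
    factors: tuple[str, ...] = HISTORY_FACTORS

    def factors_at(self, cell_index: int, period: str,
                   cumulative: bool = True) -> frozenset[str]:
        pi = self.periods.index(period)
        arr = self.cumulative if cumulative else self.per_period
        return frozenset(f for fi, f in enumerate(self.factors)
                         if arr[cell_index, pi, fi])

    def exclusive_arithmetic(self, period: str) -> np.ndarray:
        """Cells whose cumulative history at period end is exactly {arithmetic}."""
        pi = self.periods.index(period)
        cum = self.cumulative[:, pi, :]
        ai = self.factors.index("arithmetic")
        others = [i for i in range(len(self.factors)) if i != ai]
        return cum[:, ai] & ~cum[:, others].any(axis=1)


def build_coding_history(
    reg: BinRegressionResult,
    periods: dict[str, range] | None = None,
    rule: str = "any_bin",
) -> CodingHistory:
    """Integrate binwise significance into per-period coding histories.

    ``rule='any_bin'`` records a factor if it is significant in at least one
    bin of the period (the primary convention); ``rule='dominant'`` keeps
    only the factor(s) with the most significant bins in that period.
    Stimulus type never enters a history.
    """
    periods = periods or {k: v for k, v in T.PERIOD_BINS.items()}
    f_idx = [reg.factors.index(f) for f in HISTORY_FACTORS if f in reg.factors]
    f_names = tuple(reg.factors[i] for i in f_idx)
    n_cells = reg.flags.shape[0]
    per_period = np.zeros((n_cells, len(periods), len(f_idx)), dtype=bool)
    bin_pos = {int(b): i for i, b in enumerate(reg.bins)}
    for pi, (_, bin_range) in enumerate(periods.items()):
        sel = [bin_pos[b] for b in bin_range if b in bin_pos]
        if not sel:
            continue
        counts = reg.flags[:, sel, :][:, :, f_idx].sum(axis=1)  # cells x factors
        if rule == "any_bin":
            per_period[:, pi, :] = counts > 0
        elif rule == "dominant":
            best = counts.max(axis=1, keepdims=True)
            per_period[:, pi, :] = (counts > 0) & (counts == best)
        else:
            raise ValueError(f"unknown history rule {rule!r}")
    cumulative = np.logical_or.accumulate(per_period, axis=1)
    return CodingHistory(reg.cell_ids, tuple(periods), per_period, cumulative,
                         factors=f_names)


def instructed_task_filter(
    candidates: np.ndarray,
    instructed_reg: BinRegressionResult,
) -> tuple[np.ndarray, np.ndarray]:
    """Second filter: arithmetic candidates must also differentiate the +/-
    instruction in at least one 100-ms instruction-period bin.

    Returns (selective, unevaluable) boolean arrays over cells; unevaluable
    cells (no instructed-task estimate) are never selective.
    """
    candidates = np.asarray(candidates, dtype=bool)
    sig_any = instructed_reg.flags[:, :, 0].any(axis=1)
    unevaluable = np.isnan(instructed_reg.pvals[:, :, 0]).all(axis=1)
    return candidates & sig_any & ~unevaluable, candidates & unevaluable


def categorize_cells(
    history: CodingHistory,
    selective: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Category flags (overlap allowed) from preoperational coding history."""
    pi = history.periods.index("preop")
    flags = history.per_period[:, pi, :]
    tab = pd.DataFrame({
        "cell_id": history.cell_ids,
        "arithmetic_related": flags[:, history.factors.index("arithmetic")],
        "hand_related": flags[:, history.factors.index("hand")],
        "step_related": flags[:, history.factors.index("step")],
    })
    if selective is not None:
        tab["arithmetic_selective"] = np.asarray(selective, bool) & tab[
            "arithmetic_related"].to_numpy()
    counts = {c: int(tab[c].sum()) for c in tab.columns if c != "cell_id"}
    counts["total"] = len(tab)
    return tab, counts


def period_selectivity_tracking(
    history: CodingHistory,
    arithmetic_cells: np.ndarray,
    start_period: str = "preop",
    end_period: str = "operation",
) -> dict:
    """Exclusive-arithmetic status at two period ends, with exact McNemar p.

    Histories are cumulative, so a cell can lose but never regain exclusive
    status; the McNemar test quantifies the drop.
    """
    from .behavior import mcnemar_consistency

    mask = np.asarray(arithmetic_cells, dtype=bool)
    excl_start = history.exclusive_arithmetic(start_period)[mask]
    excl_end = history.exclusive_arithmetic(end_period)[mask]
    b = int((excl_start & ~excl_end).sum())   # lost exclusivity
    c = int((~excl_start & excl_end).sum())   # gained (impossible: cumulative)
    n = int(mask.sum())
    return {
        "n_cells": n,
        "exclusive_start": int(excl_start.sum()),
        "exclusive_end": int(excl_end.sum()),
        "fraction_start": float(excl_start.mean()) if n else np.nan,
        "fraction_end": float(excl_end.mean()) if n else np.nan,
        "discordant": (b, c),
        "mcnemar_p": mcnemar_consistency((b, c)),
    }
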