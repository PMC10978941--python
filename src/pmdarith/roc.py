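"""Sliding-window ROC selectivity and population-dynamics summaries.

Per cell, factor and 100-ms bin, the area under the ROC curve (equivalently
the normalised Mann-Whitney U statistic) measures how well firing rates
separate the two factor levels: 0.5 = no preference, values toward 1 prefer
addition / right hand / 1 step, toward 0 the complementary levels. The
population summaries are (i) 95% confidence ellipses of the per-cell AUC
cloud projected on factor planes, (ii) across-cell AUC variance per bin
normalised to its period mean (relative variance), and (iii) the
simultaneous arithmetic-and-hand coder selection by permutation test with
its quadrant time course (the addition<->right-hand bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import task as T
from .behavior import binomial_tail_test
from .population import BinnedPopulation

POSITIVE_CLASS = {"arithmetic": T.ADDITION, "hand": T.RIGHT, "step": 1}
CHI2_95_2DF = 5.991464547107979  # chi-square 95th percentile, 2 df


def auc_mann_whitney(values_pos: np.ndarray, values_neg: np.ndarray) -> float:
    """AUC = [#(pos > neg) + 0.5 #(pos = neg)] / (n_pos * n_neg)."""
    pos = np.asarray(values_pos, float)
    neg = np.asarray(values_neg, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _auc_from_ranks(ranks: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """AUC per cell x bin given tie-averaged ranks along the trial axis."""
    n_pos = int(pos_mask.sum())
    n_neg = pos_mask.size - n_pos
    r_pos = ranks[:, pos_mask, :].sum(axis=1)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class ROCTrajectory:
    """AUC per cell x factor x bin with per-class trial counts."""

    auc: np.ndarray                 # cells x factors x bins (NaN = class-starved)
    cell_ids: np.ndarray
    factors: tuple[str, ...]
    n_pos: dict[str, int]
    n_neg: dict[str, int]

    def factor_index(self, factor: str) -> int:
        return self.factors.index(factor)

    def to_frame(self) -> pd.DataFrame:
        cells, factors, bins = self.auc.shape
        rows = []
        for ci in range(cells):
            for fi, f in enumerate(factors_ := self.factors):
                for b in range(bins):
                    rows.append((self.cell_ids[ci], f, b, self.auc[ci, fi, b],
                                 self.n_pos[f], self.n_neg[f]))
        return pd.DataFrame(rows, columns=["cell_id", "factor", "bin", "auc",
                                           "n_pos", "n_neg"])


def class_masks(trials: pd.DataFrame,
                factors: tuple[str, ...]) -> dict[str, np.ndarray]:
    return {f: (trials[f] == POSITIVE_CLASS[f]).to_numpy() for f in factors}


def roc_trajectories(
    pop: BinnedPopulation,
    cells: np.ndarray | None = None,
    factors: tuple[str, ...] = ("arithmetic", "hand", "step"),
    min_per_class: int = 5,
) -> ROCTrajectory:
    """AUC time series for each cell and factor over all concern-period bins."""
    pop = pop.subset_valid()
    counts = pop.counts if cells is None else pop.counts[np.asarray(cells)]
    cell_ids = pop.cell_ids if cells is None else pop.cell_ids[np.asarray(cells)]
    ranks = stats.rankdata(counts, axis=1, method="average")
    masks = class_masks(pop.trials, factors)
    auc = np.full((counts.shape[0], len(factors), counts.shape[2]), np.nan)
    n_pos, n_neg = {}, {}
    for fi, f in enumerate(factors):
        m = masks[f]
        n_pos[f], n_neg[f] = int(m.sum()), int((~m).sum())
        if min(n_pos[f], n_neg[f]) < min_per_class:
            continue
        auc[:, fi, :] = _auc_from_ranks(ranks, m)
    return ROCTrajectory(auc, cell_ids, factors, n_pos, n_neg)


@dataclass
class EllipseFit:
    """2-D Gaussian summary of an AUC scatter: 95% confidence contour."""

    mean: np.ndarray
    cov: np.ndarray
    theta_deg: float        # long-axis angle in [0, 90] from the first axis
    axis_ratio: float       # long/short semi-axis, >= 1
    n: int
    level: float = 0.95
    degenerate: bool = False

    @property
    def mahalanobis2(self) -> float:
        return CHI2_95_2DF


def fit_confidence_ellipse(points: np.ndarray) -> EllipseFit:
    """Sample-mean/covariance Gaussian fit; contour at Mahalanobis^2 = 5.991."""
    pts = np.asarray(points, float)
    pts = pts[~np.isnan(pts).any(axis=1)]
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)       # ascending
    degenerate = evals[0] <= 1e-12 * max(evals[1], 1e-30)
    v = evecs[:, 1]                          # principal axis
    ang = np.degrees(np.arctan2(v[1], v[0])) % 180.0
    theta = 180.0 - ang if ang > 90.0 else ang
    ratio = float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else np.inf
    return EllipseFit(mean, cov, float(theta), ratio, n=len(pts),
                      degenerate=bool(degenerate))


def relative_variance(traj: ROCTrajectory, factor: str) -> np.ndarray:
    """Across-cell AUC variance per bin, normalised to its mean over bins.

    The normalisation makes the series mean exactly 1, so the curve shows
    *when* a factor's population selectivity spreads out, not how much.
    """
    fi = traj.factor_index(factor)
    a = traj.auc[:, fi, :]
    var = np.nanvar(a, axis=0, ddof=1)
    denom = np.nanmean(var)
    if not np.isfinite(denom) or denom == 0:
        raise ValueError(f"no usable AUC values for factor {factor!r}")
    return var / denom


def select_simultaneous_coders(
    pop: BinnedPopulation,
    cells: np.ndarray,
    factors: tuple[str, str] = ("arithmetic", "hand"),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation selection of cells coding both factors within the trial.

    Test statistic per factor: the concern-period maximum of |AUC - 0.5|.
    The null shuffles that factor's trial labels ``n_perm`` times (the
    tie-averaged rank matrix is label-free, so shuffled AUCs come from a
    single tensor contraction). p = (1 + #{null >= obs}) / (1 + n_perm); a
    cell is selected when both factors reach p < alpha. Reported AUC
    coordinates are taken at each factor's most extreme bin.
    """
    pop = pop.subset_valid()
    cells = np.asarray(cells)
    counts = pop.counts[cells]
    ranks = stats.rankdata(counts, axis=1, method="average")
    rng = np.random.default_rng(seed)
    masks = class_masks(pop.trials, factors)

    out = {"cell_id": pop.cell_ids[cells]}
    selected = np.ones(len(cells), dtype=bool)
    for f in factors:
        m = masks[f]
        if min(m.sum(), (~m).sum()) == 0:
            raise ValueError(f"factor {f!r} has an empty class")
        auc = _auc_from_ranks(ranks, m)                      # cells x bins
        dev = np.abs(auc - 0.5)
        obs = dev.max(axis=1)
        best_bin = dev.argmax(axis=1)
        # permutation null: shuffle which trials are the positive class
        perm = np.empty((n_perm, m.size), dtype=bool)
        for r in range(n_perm):
            perm[r] = rng.permutation(m)
        n_pos = int(m.sum())
        n_neg = m.size - n_pos
        r_pos = np.einsum("ctb,pt->cpb", ranks, perm.astype(float))
        null_auc = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        null_stat = np.abs(null_auc - 0.5).max(axis=2)       # cells x n_perm
        p = (1.0 + (null_stat >= obs[:, None]).sum(axis=1)) / (1.0 + n_perm)
        out[f"auc_{f}"] = auc[np.arange(len(cells)), best_bin]
        out[f"bin_{f}"] = best_bin
        out[f"p_{f}"] = p
        selected &= p < alpha
    out["selected"] = selected
    return pd.DataFrame(out)


@dataclass
class QuadrantTimecourse:
    """Addition fraction among right- and left-hand coders over time."""

    per_bin: pd.DataFrame     # bin, hand group, n, n_addition, fraction, p
    summary: dict             # per hand group: significant bins, series p
    alpha_bin: float
    chance_series: float


def quadrant_fraction_timecourse(
    coders: pd.DataFrame,
    traj: ROCTrajectory,
    alpha_bin: float = 0.05,
    chance_series: float = 0.05,
    min_cells: int = 5,
) -> QuadrantTimecourse:
    """Quadrant composition of simultaneous coders at every bin.

    At each bin the selected cells are partitioned by the signs of
    (AUC_hand - 0.5) and (AUC_arith - 0.5); cells at exactly 0.5 on either
    axis are excluded at that bin. Within the right-hand group an upper-tail
    binomial test asks whether addition preference dominates (and within the
    left-hand group whether subtraction does). The series-level summary
    counts significant bins against a chance rate of ``chance_series``.
    """
    sel = coders.loc[coders["selected"]]
    idx = np.flatnonzero(np.isin(traj.cell_ids, sel["cell_id"].to_numpy()))
    ai, hi = traj.factor_index("arithmetic"), traj.factor_index("hand")
    a = traj.auc[idx, ai, :] - 0.5
    h = traj.auc[idx, hi, :] - 0.5
    n_bins = a.shape[1]
    rows = []
    for b in range(n_bins):
        usable = (a[:, b] != 0) & (h[:, b] != 0) & np.isfinite(a[:, b]) & np.isfinite(h[:, b])
        for hand, hmask in ((T.RIGHT, h[:, b] > 0), (T.LEFT, h[:, b] < 0)):
            grp = usable & hmask
            n = int(grp.sum())
            k_add = int((a[grp, b] > 0).sum())
            if n < min_cells:
                rows.append((b, hand, n, k_add, np.nan, np.nan))
                continue
            k = k_add if hand == T.RIGHT else n - k_add
            rows.append((b, hand, n, k_add, k_add / n,
                         binomial_tail_test(k, n, 0.5)))
    per_bin = pd.DataFrame(rows, columns=["bin", "hand", "n", "n_addition",
                                          "fraction_addition", "p"])
    summary = {}
    for hand in (T.RIGHT, T.LEFT):
        sub = per_bin[(per_bin["hand"] == hand) & per_bin["p"].notna()]
        n_sig = int((sub["p"] < alpha_bin).sum())
        n_valid = len(sub)
        summary[hand] = {
            "significant_bins": n_sig,
            "n_bins": n_valid,
            "series_p": binomial_tail_test(n_sig, n_valid, chance_series)
            if n_valid else np.nan,
        }
    return QuadrantTimecourse(per_bin, summary, alpha_bin, chance_series)
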