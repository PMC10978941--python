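"""Pseudopopulation temporal cross-training decoding.

Trials from non-simultaneously recorded cells are assembled into a balanced
pseudopopulation (each included cell contributes 10 trials for every
target x arithmetic x hand condition, 160 pseudotrials by default). A linear
maximum-margin classifier is trained on the population vector at one 100-ms
bin and tested at every bin, under tenfold cross-validation with the same
stratified fold partition for all 576 train/test pixels. Significance per
pixel is a permutation test (label shuffles, accuracy must exceed the 50th
highest of 1000 null values for p < 0.05). Cross-operation decoding reuses
the classifiers trained on one label system (e.g. addition/subtraction) to
score another (right/left hand) through a fixed bijection; the prospective /
diagonal / retrospective regions of the grid are each summarised with an
exact binomial test at a per-pixel chance rate of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from . import task as T
from .behavior import binomial_tail_test

POSITIVE_CLASS = {"arithmetic": T.ADDITION, "hand": T.RIGHT}
DEFAULT_MAPPING = {T.ADDITION: T.RIGHT, T.SUBTRACTION: T.LEFT}


@dataclass
class PseudoPopulation:
    """Condition-matched pseudotrials: cells x pseudotrials x bins."""

    X: np.ndarray
    labels: pd.DataFrame          # arithmetic, hand, target_numerosity
    source_trials: np.ndarray     # cells x pseudotrials (original trial index)
    cell_ids: np.ndarray
    reps_per_condition: int

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_pseudotrials(self) -> int:
        return self.X.shape[1]

    @property
    def n_bins(self) -> int:
        return self.X.shape[2]

    def encoded(self, label_system: str) -> np.ndarray:
        """Labels as +/-1 with the conventional positive class."""
        return np.where(
            self.labels[label_system] == POSITIVE_CLASS[label_system], 1, -1
        )


def build_pseudopopulation(
    pop,
    cells: np.ndarray | None = None,
    min_per_condition: int = 10,
    seed: int = 0,
    available: np.ndarray | None = None,
) -> PseudoPopulation:
    """Assemble the balanced pseudopopulation.

    Cells lacking ``min_per_condition`` trials for any of the 16
    target x arithmetic x hand conditions are excluded; for the rest,
    exactly ``min_per_condition`` trials per condition are sampled without
    replacement, independently per cell, and aligned by condition repetition
    across cells (the cells need not be simultaneously recorded).
    ``available`` (cells x trials bool) marks which trials each cell was
    recorded on; by default every cell shares the full trial pool.
    """
    valid_mask = pop.trials["label_valid"].to_numpy(dtype=bool)
    pop = pop.subset_valid()
    tr = pop.trials
    cells = np.arange(pop.n_cells) if cells is None else np.asarray(cells)
    if available is None:
        avail = np.ones((pop.n_cells, pop.n_trials), dtype=bool)
    else:
        avail = np.asarray(available, bool)[:, valid_mask]
    conditions = [
        (t, a, h)
        for t in range(1, 5)
        for a in (T.ADDITION, T.SUBTRACTION)
        for h in (T.LEFT, T.RIGHT)
    ]
    groups = {}
    for cond in conditions:
        t, a, h = cond
        m = (
            (tr["target_numerosity"].astype("Int64") == t)
            & (tr["arithmetic"] == a)
            & (tr["hand"] == h)
        )
        groups[cond] = np.flatnonzero(m.to_numpy())
    keep = [
        c for c in cells
        if all(avail[c, g].sum() >= min_per_condition for g in groups.values())
    ]
    if not keep:
        short = {c: len(v) for c, v in groups.items() if len(v) < min_per_condition}
        raise ValueError(
            f"no cells meet the {min_per_condition}-per-condition criterion"
            + (f"; short conditions in the trial pool: {short}" if short else "")
        )
    rng = np.random.default_rng(seed)
    n_pt = len(conditions) * min_per_condition
    X = np.empty((len(keep), n_pt, pop.n_bins))
    source = np.empty((len(keep), n_pt), dtype=int)
    rows = [cond for cond in conditions for _ in range(min_per_condition)]
    for k, cell in enumerate(keep):
        for ci, cond in enumerate(conditions):
            g = groups[cond][avail[cell, groups[cond]]]
            pick = rng.choice(g, size=min_per_condition, replace=False)
            sl = slice(ci * min_per_condition, (ci + 1) * min_per_condition)
            X[k, sl] = pop.counts[cell, pick, :]
            source[k, sl] = pick
    labels = pd.DataFrame(rows, columns=["target_numerosity", "arithmetic", "hand"])
    return PseudoPopulation(X, labels, source,
                            pop.cell_ids[np.asarray(keep)], min_per_condition)


@dataclass
class DecodingGrid:
    """Cross-temporal accuracy matrix with optional permutation results."""

    accuracy: np.ndarray              # train bin x test bin
    label_train: str
    label_test: str
    folds: int
    seed: int
    bins: np.ndarray
    predictions: np.ndarray = field(repr=False, default=None)  # type: ignore
    y_test: np.ndarray = field(repr=False, default=None)  # type: ignore
    pvals: np.ndarray | None = None
    mask: np.ndarray | None = None
    null_mean: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.accuracy.shape[0]


def fold_assignment(labels: pd.DataFrame, folds: int, seed: int) -> np.ndarray:
    """Condition-stratified fold ids, reused across all grid pixels."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    key = list(zip(labels["target_numerosity"], labels["arithmetic"], labels["hand"]))
    for cond in set(key):
        idx = np.flatnonzero([k == cond for k in key])
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % folds
    return fold


def _fold_features(X: np.ndarray, fold: np.ndarray,
                   bins: np.ndarray) -> list[dict]:
    """Per-fold standardized features, shared by every label (re)fit.

    z-scoring per cell uses training-split statistics only; the arrays are
    label-free, so permutation replicates reuse them.
    """
    out = []
    for k in np.unique(fold):
        tr, te = fold != k, fold == k
        Xtr = X[:, tr, :][:, :, bins]           # cells x n_tr x bins
        mu = Xtr.mean(axis=1, keepdims=True)
        sd = Xtr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xte = (X[:, te, :][:, :, bins] - mu) / sd
        out.append({"tr": tr, "te": te, "Xtr": (Xtr - mu) / sd, "Xte": Xte})
    return out


def _grid_predictions_from(folds: list[dict], y: np.ndarray, n_bins: int,
                           C: float) -> np.ndarray:
    """Predictions (train bin x test bin x pseudotrial); each pseudotrial is
    predicted by the fold model that held it out."""
    n_pt = y.size
    pred = np.empty((n_bins, n_bins, n_pt), dtype=np.int8)
    # liblinear primal with a loose tolerance: permutation nulls need tens of
    # thousands of fits and the decision rule is insensitive to the last 1e-4
    # of the objective
    clf = LinearSVC(C=C, dual=False, tol=1e-2, max_iter=2000)
    for fd in folds:
        y_tr = y[fd["tr"]]
        te = fd["te"]
        for bi in range(n_bins):
            clf.fit(fd["Xtr"][:, :, bi].T, y_tr)
            w = clf.coef_[0]
            b0 = clf.intercept_[0]
            scores = np.einsum("c,ctb->tb", w, fd["Xte"]) + b0  # n_te x bins
            sign = np.where(scores > 0, clf.classes_[1], clf.classes_[0])
            pred[bi][:, te] = sign.T
    return pred


def _grid_predictions(X: np.ndarray, y: np.ndarray, fold: np.ndarray,
                      bins: np.ndarray, C: float) -> np.ndarray:
    return _grid_predictions_from(_fold_features(X, fold, bins), y, len(bins), C)


def crosstemporal_decode(
    pp: PseudoPopulation,
    label_system: str = "arithmetic",
    folds: int = 10,
    seed: int = 0,
    bins: np.ndarray | None = None,
    C: float = 1.0,
) -> DecodingGrid:
    """Tenfold cross-validated accuracy for every train/test bin pair."""
    bins = np.asarray(bins if bins is not None else range(pp.n_bins))
    y = pp.encoded(label_system)
    fold = fold_assignment(pp.labels, folds, seed)
    if (np.array([np.unique(y[fold == k]).size for k in range(folds)]) < 2).any():
        raise ValueError("a fold lost one class; increase trials or reduce folds")
    pred = _grid_predictions(pp.X, y, fold, bins, C)
    acc = (pred == y).mean(axis=2)
    return DecodingGrid(acc, label_system, label_system, folds, seed, bins,
                        predictions=pred, y_test=y)


def cross_operation_decode(
    pp: PseudoPopulation,
    trained_on: str = "arithmetic",
    tested_on: str = "hand",
    mapping: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    bins: np.ndarray | None = None,
    C: float = 1.0,
) -> DecodingGrid:
    """Reuse classifiers trained on one label system to score another.

    ``mapping`` is a bijection from trained-on levels to tested-on levels
    (default addition->right, subtraction->left). Classifiers and folds are
    identical to the within-system analysis; only the scoring labels change,
    so the identity mapping reproduces the within-system grid bit-exactly.
    """
    mapping = dict(mapping or DEFAULT_MAPPING)
    if tested_on == trained_on:
        levels = sorted(set(pp.labels[trained_on]))
        mapping = {l: l for l in levels}
    if sorted(mapping.values()) != sorted(set(pp.labels[tested_on])):
        raise ValueError(f"mapping {mapping} is not a bijection onto "
                         f"{tested_on} levels")
    grid = crosstemporal_decode(pp, trained_on, folds=folds, seed=seed,
                                bins=bins, C=C)
    # does the mapping send the trained positive class to the tested one?
    flip = 1 if mapping[POSITIVE_CLASS[trained_on]] == POSITIVE_CLASS[tested_on] else -1
    y_test = flip * pp.encoded(tested_on)
    acc = (grid.predictions == y_test).mean(axis=2)
    return replace(grid, accuracy=acc, label_test=tested_on, y_test=y_test)


def permutation_significance(
    pp: PseudoPopulation,
    grid: DecodingGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    refit: bool | None = None,
    C: float = 1.0,
) -> DecodingGrid:
    """Per-pixel permutation test of the decoding grid.

    One label shuffle per replicate is reused across all pixels. By default
    (``refit=True``) the training labels are shuffled and the classifier is
    retrained each replicate, and the refit predictions are scored against
    the grid's own test labels (for a within-system grid these are the
    shuffled labels themselves; for a cross-operation grid they stay the
    true mapped labels, so the null includes the incidental transfer that
    classifier weight noise produces). ``refit=False`` is a cheaper
    alternative that holds the trained predictions fixed and shuffles the
    tested labels. A pixel is significant when its observed accuracy
    strictly exceeds the ``round(alpha * n_perm)``-th highest null accuracy;
    ties count as non-significant. p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    if refit is None:
        refit = True
    rng = np.random.default_rng(seed)
    cross_system = grid.label_test != grid.label_train
    null = np.empty((n_perm, grid.n_bins, grid.n_bins))
    if refit:
        y = pp.encoded(grid.label_train)
        fold = fold_assignment(pp.labels, grid.folds, grid.seed)
        folds = _fold_features(pp.X, fold, grid.bins)
        for r in range(n_perm):
            y_perm = rng.permutation(y)
            pred = _grid_predictions_from(folds, y_perm, grid.n_bins, C)
            y_score = grid.y_test if cross_system else y_perm
            null[r] = (pred == y_score).mean(axis=2)
    else:
        # label classes are balanced, so the shuffled-label null does not
        # depend on the bijection's sign convention
        for r in range(n_perm):
            y_perm = rng.permutation(grid.y_test)
            null[r] = (grid.predictions == y_perm).mean(axis=2)
    k = max(1, int(round(alpha * n_perm)))
    null_sorted = np.sort(null, axis=0)[::-1]     # descending
    thresh = null_sorted[k - 1]
    mask = grid.accuracy > thresh
    pvals = (1.0 + (null >= grid.accuracy[None]).sum(axis=0)) / (1.0 + n_perm)
    return replace(grid, pvals=pvals, mask=mask, null_mean=null.mean(axis=0))


@dataclass
class CrossOpSummary:
    """Significant-pixel counts per grid region with binomial series tests."""

    diagonal: dict
    prospective: dict
    retrospective: dict

    def as_dict(self) -> dict:
        return {"diagonal": self.diagonal, "prospective": self.prospective,
                "retrospective": self.retrospective}


def grid_regions(n_bins: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pixel index sets: diagonal (n), prospective and retrospective
    (n(n-1)/2 each; training precedes / follows testing)."""
    iu = np.triu_indices(n_bins, k=1)
    il = np.tril_indices(n_bins, k=-1)
    di = (np.arange(n_bins), np.arange(n_bins))
    return {"diagonal": di, "prospective": iu, "retrospective": il}


def prospective_retrospective_summary(
    grid: DecodingGrid, p_chance: float = 0.05
) -> CrossOpSummary:
    """Binomial summary of significant pixels in the three grid regions."""
    if grid.mask is None:
        raise ValueError("run permutation_significance first")
    out = {}
    for name, idx in grid_regions(grid.n_bins).items():
        total = len(idx[0])
        count = int(grid.mask[idx].sum())
        out[name] = {
            "significant": count,
            "total": total,
            "fraction": count / total,
            "p": binomial_tail_test(count, total, p_chance),
        }
    return CrossOpSummary(out["diagonal"], out["prospective"], out["retrospective"])
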