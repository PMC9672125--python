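"""Slice-based evaluation, cross-validation folds, and nonparametric tests.

Evaluation is slice-based: confusion counts (TP/TN/FP/FN) are computed on
every 2D slice along one axis (axial by default, the acquisition plane)
and six metrics are derived per slice:

    Ac  = (TP + TN) / (FP + TP + FN + TN)
    DSC = 2 TP / (FP + 2 TP + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    PPV = TP / (TP + FP)
    NPV = TN / (TN + FN)

A metric whose denominator is zero on a slice is *undefined*, with one
deliberate exception: a slice whose ground truth is empty but which
carries false positives has DSC exactly 0 (the formula already gives
0/positive) — so stray predictions on tooth-free slices are punished.
A slice where both prediction and ground truth are empty has an undefined
0/0 DSC; by default the aggregate scores it as 1 (nothing to find,
nothing found), configurable to exclusion instead.  Undefined Sn/Sp/PPV/
NPV slices are excluded from that metric's aggregate.

The statistical helpers mirror a standard nonparametric workflow:
Lilliefors/Kolmogorov-Smirnov normality screen, paired Wilcoxon
signed-rank for before/after comparisons, and Kruskal-Wallis with Dunn's
Bonferroni-corrected post hoc for multi-group comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import (
    ConsistencyError,
    DataError,
    DegenerateDataError,
    ParameterError,
)
from .io_preprocess import BinaryMask
from .views import VIEW_AXIS

METRIC_NAMES = ("dsc", "ac", "sn", "sp", "ppv", "npv")


@dataclass
class SliceMetrics:
    """Confusion counts and the six derived metrics for one slice.

    Undefined metrics (zero denominator) are stored as ``None``.
    """

    slice_index: int
    tp: int
    tn: int
    fp: int
    fn: int
    dsc: float | None = field(init=False)
    ac: float | None = field(init=False)
    sn: float | None = field(init=False)
    sp: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)

    def __post_init__(self) -> None:
        tp, tn, fp, fn = self.tp, self.tn, self.fp, self.fn
        self.dsc = _ratio(2 * tp, fp + 2 * tp + fn)
        self.ac = _ratio(tp + tn, fp + tp + fn + tn)
        self.sn = _ratio(tp, tp + fn)
        self.sp = _ratio(tn, tn + fp)
        self.ppv = _ratio(tp, tp + fp)
        self.npv = _ratio(tn, tn + fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_per_slice(
    pred: BinaryMask, gt: BinaryMask, axis: str = "axial"
) -> list[SliceMetrics]:
    """Per-slice confusion counts and metrics along one view axis."""
    if pred.shape != gt.shape:
        raise ConsistencyError(
            f"prediction {pred.shape} and ground truth {gt.shape} disagree"
        )
    if axis not in VIEW_AXIS:
        raise ParameterError(f"unknown axis {axis!r}")
    ax = VIEW_AXIS[axis]
    p = np.moveaxis(pred.data, ax, 0).reshape(pred.shape[ax], -1)
    g = np.moveaxis(gt.data, ax, 0).reshape(gt.shape[ax], -1)
    tp = (p & g).sum(axis=1)
    fp = (p & ~g).sum(axis=1)
    fn = (~p & g).sum(axis=1)
    tn = (~p & ~g).sum(axis=1)
    return [
        SliceMetrics(slice_index=k, tp=int(tp[k]), tn=int(tn[k]),
                     fp=int(fp[k]), fn=int(fn[k]))
        for k in range(p.shape[0])
    ]


def metrics_frame(slices: Sequence[SliceMetrics]) -> pd.DataFrame:
    """Tabulate per-slice results (one row per slice)."""
    rows = [
        {
            "slice": s.slice_index, "tp": s.tp, "tn": s.tn, "fp": s.fp, "fn": s.fn,
            **{m: getattr(s, m) for m in METRIC_NAMES},
        }
        for s in slices
    ]
    return pd.DataFrame(rows)


def aggregate(
    slices: Sequence[SliceMetrics],
    how: Literal["mean", "median", "both"] = "mean",
    empty_empty_dsc: Literal["one", "exclude"] = "one",
) -> dict[str, float | dict[str, float]]:
    """Summarise per-slice metrics over a stack of slices.

    ``empty_empty_dsc`` controls the 0/0 DSC slices (empty GT, empty
    prediction): ``"one"`` scores them as a perfect 1, ``"exclude"`` drops
    them.  Slices where another metric is undefined are always excluded
    from that metric's summary.
    """
    if not slices:
        raise DataError("cannot aggregate an empty slice list")
    if how not in ("mean", "median", "both"):
        raise ParameterError(f"unknown aggregation {how!r}")
    out: dict[str, float | dict[str, float]] = {}
    for m in METRIC_NAMES:
        vals = []
        for s in slices:
            v = getattr(s, m)
            if v is None and m == "dsc" and empty_empty_dsc == "one":
                v = 1.0
            if v is not None:
                vals.append(v)
        if not vals:
            out[m] = math.nan if how != "both" else {"mean": math.nan,
                                                     "median": math.nan}
            continue
        arr = np.asarray(vals, dtype=float)
        if how == "mean":
            out[m] = float(arr.mean())
        elif how == "median":
            out[m] = float(np.median(arr))
        else:
            out[m] = {"mean": float(arr.mean()), "median": float(np.median(arr))}
    return out


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Patient-level k-fold plan: each patient is tested exactly once."""

    subsets: dict[object, int]  # patient id -> subset number (1-based)
    folds: list[tuple[list, list]]  # (train ids, test ids) per fold


def make_folds(patient_ids: Sequence, n_folds: int = 4, seed: int = 0) -> FoldPlan:
    """Seeded equal (or nearly equal) patient partition into test subsets."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ParameterError("patient ids must be unique")
    if n_folds < 2:
        raise ParameterError("need at least 2 folds")
    if len(ids) < n_folds:
        raise DataError(f"{len(ids)} patients cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    subsets: dict[object, int] = {}
    for pos, pid in enumerate(order):
        subsets[pid] = pos % n_folds + 1
    folds = []
    for f in range(1, n_folds + 1):
        test = [pid for pid in ids if subsets[pid] == f]
        train = [pid for pid in ids if subsets[pid] != f]
        folds.append((train, test))
    return FoldPlan(subsets=subsets, folds=folds)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class StatsResult:
    test: str
    statistic: float
    p: float
    posthoc: list[tuple[tuple, float]] | None = None


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> StatsResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's convention); the p-value is
    exact for small samples without ties and a tie-corrected normal
    approximation otherwise (scipy's ``method="auto"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if nz.size < 5:
        raise DataError(
            f"only {nz.size} nonzero differences; need >= 5 for a meaningful test"
        )
    stat, p = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return StatsResult(test="wilcoxon", statistic=float(stat), p=float(p))


def kruskal_wallis_bonferroni(groups: Sequence[Sequence[float]]) -> StatsResult:
    """Kruskal-Wallis H test with Dunn's Bonferroni-corrected post hoc.

    Dunn's z for groups i, j compares mean ranks over the pooled sample
    with the tie-corrected variance; each raw two-sided p is multiplied by
    the number of pairwise comparisons (capped at 1).
    """
    if len(groups) < 3:
        raise ParameterError("need >= 3 groups (use paired_wilcoxon for two)")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ParameterError("each group needs >= 2 observations")
    h, p = stats.kruskal(*groups)

    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term for Dunn's variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_tot - 1)))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size

    pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    posthoc = []
    for i, j in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw = 2.0 * stats.norm.sf(abs(z))
        posthoc.append(((i, j), min(1.0, raw * m)))
    return StatsResult(test="kruskal_wallis", statistic=float(h), p=float(p),
                       posthoc=posthoc)


def ks_normality(x: Sequence[float]) -> StatsResult:
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    Because the normal's mean and SD come from the sample itself, the
    Lilliefors correction is used for the p-value.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise DataError(f"need >= 5 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample has no distribution to test")
    stat, p = lilliefors(x, dist="norm")
    return StatsResult(test="ks_lilliefors", statistic=float(stat), p=float(p))
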