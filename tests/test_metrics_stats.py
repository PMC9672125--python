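"""Slice metrics, aggregation policies, folds, and the statistical tests."""

import numpy as np
import pytest
from scipy import stats

from voteseg import (
    BinaryMask,
    SliceMetrics,
    aggregate,
    confusion_per_slice,
    kruskal_wallis_bonferroni,
    ks_normality,
    make_folds,
    metrics_frame,
    paired_wilcoxon,
)
from voteseg.errors import (
    ConsistencyError,
    DataError,
    DegenerateDataError,
    ParameterError,
)


# ---------------------------------------------------------------------------
# Per-slice confusion and metrics
# ---------------------------------------------------------------------------


def test_perfect_prediction_scores_one(random_mask):
    gt = random_mask(shape=(10, 10, 6))
    for s in confusion_per_slice(gt, gt):
        for m in ("dsc", "ac", "sn", "sp", "ppv", "npv"):
            v = getattr(s, m)
            assert v is None or v == 1.0


def test_dsc_by_substitution():
    """tp=2, fp=1, fn=1 on one slice: DSC = 2*2/(1+4+1) = 2/3."""
    gt = np.zeros((4, 4, 1), dtype=bool)
    pred = np.zeros((4, 4, 1), dtype=bool)
    gt[0, 0] = gt[0, 1] = gt[0, 2] = True  # 3 positives
    pred[0, 0] = pred[0, 1] = True  # 2 tp
    pred[3, 3] = True  # 1 fp
    (s,) = confusion_per_slice(BinaryMask(pred), BinaryMask(gt))
    assert (s.tp, s.fp, s.fn) == (2, 1, 1)
    assert s.dsc == pytest.approx(2 / 3)
    assert s.ac == pytest.approx(14 / 16)


def test_fp_on_empty_gt_slice_scores_zero_dsc():
    """A stray prediction on a tooth-free slice zeroes that slice's DSC."""
    gt = BinaryMask(np.zeros((5, 5, 3), dtype=bool))
    pred = np.zeros((5, 5, 3), dtype=bool)
    pred[2, 2, 1] = True
    slices = confusion_per_slice(BinaryMask(pred), gt)
    assert slices[1].dsc == 0.0
    assert slices[0].dsc is None and slices[2].dsc is None  # 0/0 undefined


def test_counts_conserve_whole_volume_totals(rng):
    pred = BinaryMask(rng.random((9, 10, 11)) < 0.4)
    gt = BinaryMask(rng.random((9, 10, 11)) < 0.4)
    whole = {
        "tp": int((pred.data & gt.data).sum()),
        "fp": int((pred.data & ~gt.data).sum()),
        "fn": int((~pred.data & gt.data).sum()),
        "tn": int((~pred.data & ~gt.data).sum()),
    }
    for axis in ("axial", "coronal", "sagittal"):
        slices = confusion_per_slice(pred, gt, axis=axis)
        for key in whole:
            assert sum(getattr(s, key) for s in slices) == whole[key]
        per_slice = pred.shape[0] * pred.shape[1] * pred.shape[2] // len(slices)
        assert all(s.tp + s.tn + s.fp + s.fn == per_slice for s in slices)


def test_harmonic_identity_dsc_ppv_sn(rng):
    pred = BinaryMask(rng.random((8, 8, 12)) < 0.5)
    gt = BinaryMask(rng.random((8, 8, 12)) < 0.5)
    for s in confusion_per_slice(pred, gt):
        if s.ppv is not None and s.sn is not None and (s.ppv + s.sn) > 0:
            assert s.dsc == pytest.approx(2 * s.ppv * s.sn / (s.ppv + s.sn))


def test_swapping_pred_and_gt_swaps_metrics(rng):
    pred = BinaryMask(rng.random((8, 8, 4)) < 0.5)
    gt = BinaryMask(rng.random((8, 8, 4)) < 0.5)
    fwd = confusion_per_slice(pred, gt)
    rev = confusion_per_slice(gt, pred)
    for a, b in zip(fwd, rev):
        assert a.sn == b.ppv and a.ppv == b.sn
        assert a.sp == b.npv and a.npv == b.sp
        assert a.dsc == b.dsc and a.ac == b.ac


def test_shape_mismatch_rejected():
    with pytest.raises(ConsistencyError):
        confusion_per_slice(
            BinaryMask(np.zeros((3, 3, 3), bool)),
            BinaryMask(np.zeros((3, 3, 4), bool)),
        )


def test_metrics_frame_columns(random_mask):
    df = metrics_frame(confusion_per_slice(random_mask(), random_mask()))
    assert list(df.columns) == [
        "slice", "tp", "tn", "fp", "fn", "dsc", "ac", "sn", "sp", "ppv", "npv"
    ]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _slice_with(tp, tn, fp, fn, idx=0):
    return SliceMetrics(slice_index=idx, tp=tp, tn=tn, fp=fp, fn=fn)


def test_aggregate_mean_median_arithmetic():
    s1 = _slice_with(tp=1, tn=0, fp=1, fn=2)  # dsc 2/(1+2+2)=0.4
    s2 = _slice_with(tp=2, tn=0, fp=1, fn=0)  # dsc 4/5=0.8
    out = aggregate([s1, s2], how="both")
    assert out["dsc"]["mean"] == pytest.approx(0.6)
    assert out["dsc"]["median"] == pytest.approx(0.6)


def test_aggregate_excludes_undefined_sensitivity():
    defined = _slice_with(tp=9, tn=0, fp=0, fn=1)  # sn 0.9
    undefined = _slice_with(tp=0, tn=5, fp=2, fn=0)  # no gt positives
    out = aggregate([defined, undefined], how="mean")
    assert out["sn"] == pytest.approx(0.9)


def test_aggregate_empty_empty_dsc_policies():
    perfect_empty = _slice_with(tp=0, tn=25, fp=0, fn=0)
    half = _slice_with(tp=1, tn=0, fp=2, fn=0)  # dsc 0.5
    assert aggregate([perfect_empty, half], "mean")["dsc"] == pytest.approx(0.75)
    assert aggregate([perfect_empty, half], "mean",
                     empty_empty_dsc="exclude")["dsc"] == pytest.approx(0.5)


def test_aggregate_median_order_statistic():
    slices = [_slice_with(tp=k, tn=0, fp=100 - k, fn=100 - k, idx=k)
              for k in range(101)]  # dsc = 2k/(2k + 2(100-k)) = k/100
    out = aggregate(slices, how="median")
    assert out["dsc"] == pytest.approx(0.5)


def test_aggregate_empty_list_rejected():
    with pytest.raises(DataError):
        aggregate([], "mean")


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def test_folds_equal_partition_24_patients():
    ids = [f"p{i:02d}" for i in range(24)]
    plan = make_folds(ids, n_folds=4, seed=3)
    sizes = [sum(1 for s in plan.subsets.values() if s == f) for f in (1, 2, 3, 4)]
    assert sizes == [6, 6, 6, 6]
    tested = [pid for _, test in plan.folds for pid in test]
    assert sorted(tested) == sorted(ids)  # each patient tested exactly once
    for train, test in plan.folds:
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)


def test_folds_deterministic_and_small_cases():
    ids = list(range(8))
    a = make_folds(ids, 4, seed=11)
    b = make_folds(ids, 4, seed=11)
    assert a.subsets == b.subsets
    assert all(len(test) == 2 for _, test in a.folds)
    with pytest.raises(DataError):
        make_folds([1, 2, 3], 4)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def test_wilcoxon_degenerate_on_identical_samples(rng):
    x = rng.normal(size=10)
    with pytest.raises(DegenerateDataError):
        paired_wilcoxon(x, x)


def test_wilcoxon_constant_shift_exact_p():
    x = np.arange(10, dtype=float)
    res = paired_wilcoxon(x, x + 1.0)
    assert res.statistic == 0.0
    assert res.p == pytest.approx(2 / 2**10)


def test_wilcoxon_needs_five_nonzero_diffs():
    x = np.zeros(10)
    y = np.zeros(10)
    y[:3] = 1.0
    with pytest.raises(DataError):
        paired_wilcoxon(x, y)


def test_kruskal_identical_groups_null():
    res = kruskal_wallis_bonferroni([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_kruskal_blocked_ranks_hand_value():
    """Ranks 1-9 in blocks of 3: H = 12/(9*10) * 3*((2-5)^2+(5-5)^2+(8-5)^2)."""
    res = kruskal_wallis_bonferroni([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.statistic == pytest.approx(7.2)
    assert res.p == pytest.approx(stats.chi2.sf(7.2, df=2))


def test_kruskal_bonferroni_pair_count_and_arithmetic(rng):
    groups = [rng.normal(loc=i * 0.1, size=8) for i in range(9)]
    res = kruskal_wallis_bonferroni(groups)
    assert len(res.posthoc) == 36  # C(9,2)
    # recompute one raw Dunn p and check the min(1, 36*raw) adjustment
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    mean_ranks = [ranks[i * 8:(i + 1) * 8].mean() for i in range(9)]
    var = n * (n + 1) / 12.0  # no ties in continuous draws
    z = (mean_ranks[0] - mean_ranks[1]) / np.sqrt(var * (2 / 8))
    raw = 2 * stats.norm.sf(abs(z))
    (pair, adj) = res.posthoc[0]
    assert pair == (0, 1)
    assert adj == pytest.approx(min(1.0, raw * 36))


def test_kruskal_needs_three_groups():
    with pytest.raises(ParameterError):
        kruskal_wallis_bonferroni([[1, 2], [3, 4]])


def test_ks_normality_degenerate_constant():
    with pytest.raises(DegenerateDataError):
        ks_normality(np.ones(20))
    with pytest.raises(DataError):
        ks_normality([1.0, 2.0, 3.0])


def test_ks_normality_simulation_calibration():
    """Normal data is rejected at roughly the nominal rate; uniform data
    is nearly always rejected at n = 1000."""
    rng = np.random.default_rng(42)
    reps = 100
    normal_reject = sum(
        ks_normality(rng.normal(size=1000)).p < 0.05 for _ in range(reps)
    )
    uniform_reject = sum(
        ks_normality(rng.uniform(size=1000)).p < 0.05 for _ in range(reps)
    )
    # nominal 5% level within 3 binomial SE over 100 reps (~6.5)
    assert normal_reject <= 0.05 * reps + 3 * np.sqrt(reps * 0.05 * 0.95)
    assert uniform_reject >= 0.95 * reps
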