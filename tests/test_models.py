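"""Network construction, callbacks, training behaviour, and inference."""

from types import SimpleNamespace

import numpy as np
import pytest

from voteseg import (
    DegradationConfig,
    ModelSpec,
    PhantomConfig,
    PlateauSchedule,
    Volume,
    aggregate,
    binarize,
    build_predictor,
    confusion_per_slice,
    make_phantom,
    predict_volume,
    train,
)
from voteseg.errors import DataError, ParameterError, SpecError


def small_spec(**kw):
    base = dict(mode="2d", depth=2, first_features=8, input_shape=(32, 32, 1),
                lr0=3e-3, batch=4, epochs=5)
    base.update(kw)
    return ModelSpec(**base)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def test_parameter_count_matches_hand_tally():
    """Layer-by-layer tally for depth 2, 8 first features, 1 input channel."""
    def conv(cin, cout, k):
        return cout * cin * k + cout  # weights + biases

    tally = (
        conv(1, 8, 9) + conv(8, 8, 9)        # encoder level 0
        + conv(8, 16, 9) + conv(16, 16, 9)   # bottleneck level 1
        + conv(16, 8, 9)                     # up-convolution
        + conv(16, 8, 9) + conv(8, 8, 9)     # decoder level 0 (after concat)
        + conv(8, 2, 1)                      # dual-class 1x1 head
    )
    pred = build_predictor(small_spec(), seed=0)
    assert pred.n_params() == tally


def test_table_defaults_by_mode():
    for mode, (shape, batch, epochs) in {
        "2d": ((512, 512, 1), 12, 150),
        "2.5d": ((512, 512, 3), 12, 150),
        "3d": ((64, 64, 128), 6, 200),
    }.items():
        spec = ModelSpec(mode=mode)
        assert spec.input_shape == shape
        assert (spec.batch, spec.epochs) == (batch, epochs)
        assert spec.depth == 4 and spec.first_features == 32
        assert spec.lr0 == 1e-4 and spec.lr_decay_factor == 0.95
        assert spec.lr_patience == 10 and spec.early_stop_patience == 50


def test_same_seed_same_initial_predictions(rng):
    x = rng.normal(size=(32, 32))
    a = build_predictor(small_spec(), seed=9)
    b = build_predictor(small_spec(), seed=9)
    np.testing.assert_array_equal(a.forward(x[None]), b.forward(x[None]))
    c = build_predictor(small_spec(), seed=10)
    assert not np.array_equal(a.forward(x[None]), c.forward(x[None]))


def test_indivisible_input_shape_rejected():
    with pytest.raises(SpecError):
        build_predictor(ModelSpec(mode="2d", depth=4, input_shape=(50, 50, 1)))


# ---------------------------------------------------------------------------
# Callbacks
# ---------------------------------------------------------------------------


def test_plateau_schedule_frozen_loss_arithmetic():
    """Frozen validation loss: LR decays by 0.95 every 10 epochs and
    training stops at epoch 50."""
    sched = PlateauSchedule(lr0=1e-4, factor=0.95, lr_patience=10,
                            stop_patience=50)
    sched.set_baseline(1.0)
    lrs, stop_at = [], None
    for epoch in range(1, 61):
        lr, stop = sched.update(1.0)
        lrs.append(lr)
        if stop and stop_at is None:
            stop_at = epoch
            break
    assert lrs[9] == pytest.approx(1e-4 * 0.95)
    assert lrs[19] == pytest.approx(1e-4 * 0.95**2)
    assert stop_at == 50


def test_plateau_schedule_resets_on_improvement():
    sched = PlateauSchedule(lr0=1.0, factor=0.5, lr_patience=3, stop_patience=6)
    sched.set_baseline(1.0)
    for loss in (1.0, 1.0, 0.9, 1.0, 1.0):  # improvement at step 3
        lr, stop = sched.update(loss)
    assert lr == 1.0 and not stop
    lr, stop = sched.update(1.0)  # third stalled epoch since the best
    assert lr == 0.5


def _tiny_pairs(n=4, size=32, seed=0):
    r = np.random.default_rng(seed)
    xs = r.normal(size=(n, size, size)) * 100
    ts = (r.random((n, size, size)) < 0.3).astype(int)
    return list(zip(xs, ts))


def test_history_bookkeeping_one_epoch():
    pairs = _tiny_pairs()
    pred = build_predictor(small_spec(epochs=1), seed=0)
    _, hist = train(pred, pairs, pairs)
    assert len(hist) == 1
    assert set(hist[0]) == {"epoch", "train_loss", "val_loss", "lr"}
    assert hist[0]["lr"] == pytest.approx(3e-3)


def test_training_determinism():
    pairs = _tiny_pairs()
    h1 = train(build_predictor(small_spec(epochs=2), 5), pairs, pairs, seed=1)[1]
    h2 = train(build_predictor(small_spec(epochs=2), 5), pairs, pairs, seed=1)[1]
    assert h1 == h2


def test_early_stop_on_stalled_validation():
    """With a vanishing learning rate the validation loss never improves,
    so training must halt after exactly stop_patience epochs."""
    pairs = _tiny_pairs()
    spec = small_spec(lr0=1e-30, epochs=20, early_stop_patience=4, lr_patience=2)
    pred = build_predictor(spec, seed=0)
    _, hist = train(pred, pairs, pairs)
    assert len(hist) == 4
    # recorded LRs follow the x0.95 rule recomputed from the recorded stalls
    assert hist[-1]["lr"] == pytest.approx(1e-30 * 0.95, rel=1e-6)


def test_train_data_contract():
    pred = build_predictor(small_spec(), seed=0)
    with pytest.raises(DataError):
        train(pred, [], _tiny_pairs())
    bad = [(np.zeros((32, 32)), np.full((32, 32), 2.0))]
    with pytest.raises(DataError):
        train(pred, bad, bad)


# ---------------------------------------------------------------------------
# Whole-volume inference
# ---------------------------------------------------------------------------


def _stub(mode, value=0.9, **spec_kw):
    spec = ModelSpec(mode=mode, depth=1, first_features=1, **spec_kw)

    def forward(x):
        return np.full(x.shape[1:], value)

    return SimpleNamespace(spec=spec, forward=forward)


def test_constant_stub_fills_probability_volume(rng):
    vol = Volume(rng.normal(size=(8, 8, 4)))
    for mode in ("2d", "2.5d"):
        out = predict_volume(_stub(mode, input_shape=(8, 8, 1)), vol)
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.data, 0.9)


def test_3d_mode_crops_padding(rng):
    vol = Volume(rng.normal(size=(70, 70, 130)))
    out = predict_volume(_stub("3d", input_shape=(64, 64, 128)), vol)
    assert out.shape == (70, 70, 130)
    np.testing.assert_allclose(out.data, 0.9)


def test_2d_axial_output_slice_depends_only_on_its_input_slice(rng):
    vol = Volume(rng.normal(size=(8, 8, 6)) * 100)
    pred = build_predictor(small_spec(input_shape=(8, 8, 1)), seed=2)
    base = predict_volume(pred, vol)
    bumped = Volume(vol.data.copy())
    bumped.data[:, :, 3] += 500.0
    out = predict_volume(pred, bumped)
    changed = [k for k in range(6)
               if not np.array_equal(out.data[:, :, k], base.data[:, :, k])]
    assert changed == [3]


def test_binarize_threshold_conventions(rng):
    vol = Volume(np.full((3, 3, 3), 0.5))
    assert binarize(vol, 0.5).data.all()  # tie goes to foreground
    assert not binarize(Volume(np.full((3, 3, 3), 0.49)), 0.5).data.any()
    probs = Volume(rng.random((6, 6, 6)))
    np.testing.assert_array_equal(binarize(probs, 0.7).data, probs.data >= 0.7)
    with pytest.raises(ParameterError):
        binarize(probs, 1.0)
    with pytest.raises(ParameterError):
        binarize(Volume(np.full((2, 2, 2), 1.5)), 0.5)


def test_end_to_end_shape_preservation(rng):
    vol = Volume(rng.normal(size=(16, 16, 8)) * 100)
    for mode, shape in [("2d", (16, 16, 1)), ("2.5d", (16, 16, 3)),
                        ("3d", (8, 8, 4))]:
        spec = ModelSpec(mode=mode, depth=2, first_features=4,
                         input_shape=shape, batch=2, epochs=1)
        pred = build_predictor(spec, seed=0)
        mask = binarize(predict_volume(pred, vol))
        assert mask.shape == vol.shape


def test_reduced_unet_learns_phantom_training_slices():
    """Smoke test of the optimisation loop: a depth-2 / 8-feature 2D net
    fits 32^3 phantom slices to training DSC > 0.8 within 30 epochs."""
    vol, gt = make_phantom(PhantomConfig(
        shape=(32, 32, 32), n_teeth=3, crown_semiaxes=(2.5, 2.5, 3.0),
        root_radius=1.5, root_length=4, seed=3))
    pairs = [(vol.data[:, :, k], gt.data[:, :, k]) for k in range(26)]
    tr, va = pairs[:20], pairs[20:]
    pred = build_predictor(small_spec(epochs=30), seed=0)
    pred, hist = train(pred, tr, va, seed=0)
    assert len(hist) <= 30
    mask = binarize(predict_volume(pred, vol))
    slices = confusion_per_slice(mask, gt)
    train_dsc = aggregate(slices[:20], how="mean")["dsc"]
    assert train_dsc > 0.8
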