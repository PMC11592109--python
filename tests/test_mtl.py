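import numpy as np
import pytest

from evquant._errors import ConfigError
from evquant.imaging import TileSet
from evquant.mtl import (
    ArchConfig,
    MultitaskSpotCounter,
    TrainConfig,
    build_model,
    predict,
    train,
    tune,
)
from evquant.mtl.train import _count_loss_grad, _evaluate, _seg_loss_grad


def _conv_params(cin, cout, k=3):
    return k * k * cin * cout + cout


def _double_conv_params(cin, cout, residual):
    n = _conv_params(cin, cout) + _conv_params(cout, cout)
    if residual and cin != cout:
        n += _conv_params(cin, cout, k=1)
    return n


def _expected_params(f, depth, hidden, residual):
    n = 0
    cin = 1
    for d in range(depth):
        n += _double_conv_params(cin, f * 2**d, residual)
        cin = f * 2**d
    cbot = f * 2**depth
    n += _conv_params(cin, cbot, k=1)  # connection block
    c_up = cbot
    for d in reversed(range(depth)):
        c_skip = f * 2**d
        n += _double_conv_params(c_up + c_skip, c_skip, residual)
        c_up = c_skip
    n += _conv_params(c_up, 1, k=1)  # segmentation head
    n += cbot * hidden + hidden + hidden * 1 + 1  # counting head
    return n


# ---------------------------------------------------------------------------
# construction


def test_output_shapes_and_nonnegative_count():
    net = build_model(ArchConfig(base_filters=4), seed=0)
    x = np.random.default_rng(0).random((3, 32, 32)).astype(np.float32)
    logits, y = net.forward(x)
    assert logits.shape == (3, 32, 32)
    assert y.shape == (3,)
    assert (y >= 0).all()  # softplus output


def test_initialisation_is_seed_deterministic():
    a = build_model(seed=5)
    b = build_model(seed=5)
    for (pa, _), (pb, _) in zip(a.params(), b.params()):
        assert np.array_equal(pa, pb)
    c = build_model(seed=6)
    assert any(
        not np.array_equal(pa, pc) for (pa, _), (pc, _) in zip(a.params(), c.params())
    )


@pytest.mark.parametrize("residual", [True, False])
def test_parameter_count_matches_layer_algebra(residual):
    arch = ArchConfig(base_filters=4, depth=2, residual=residual, regression_hidden=16)
    net = build_model(arch, seed=0)
    assert net.n_parameters() == _expected_params(4, 2, 16, residual)


def test_invalid_architectures_rejected():
    with pytest.raises(ConfigError, match="pretrained"):
        ArchConfig(pretrained=True)
    with pytest.raises(ConfigError, match="encoder"):
        ArchConfig(encoder="vgg16")
    with pytest.raises(ConfigError, match="depth"):
        ArchConfig(depth=1)


# ---------------------------------------------------------------------------
# gradients


def _promote_to_float64(net):
    convs = [net.conn, net.seg_head, net.fc1, net.fc2]
    for blk in net.enc + net.dec:
        convs += [blk.conv1, blk.conv2] + ([blk.proj] if blk.proj is not None else [])
    for c in convs:
        c.W = c.W.astype(np.float64)
        c.b = c.b.astype(np.float64)
        c.dW = np.zeros_like(c.W)
        c.db = np.zeros_like(c.b)


def test_backprop_matches_finite_differences():
    rng = np.random.default_rng(0)
    net = build_model(ArchConfig(base_filters=4, depth=2, residual=True), seed=3)
    _promote_to_float64(net)
    x = rng.random((2, 8, 8)).astype(np.float32)
    masks = rng.random((2, 8, 8)) > 0.7
    counts = np.array([3.0, 7.0])

    def loss():
        logits, y = net.forward(x)
        seg, _, _ = _seg_loss_grad(logits, masks)
        cnt, _ = _count_loss_grad(y, counts)
        return seg + 0.5 * cnt

    logits, y = net.forward(x)
    seg, dlogits, _ = _seg_loss_grad(logits, masks)
    cnt, dy = _count_loss_grad(y, counts)
    for _, g in net.params():
        g[...] = 0.0
    net.backward(dlogits, 0.5 * dy)

    rng2 = np.random.default_rng(1)
    for p, g in net.params():
        flat = p.reshape(-1)
        for _ in range(4):
            i = int(rng2.integers(flat.size))
            old = flat[i]
            eps = 1e-6
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = g.reshape(-1)[i]
            assert abs(num - ana) <= 1e-4 + 1e-3 * abs(num)


# ---------------------------------------------------------------------------
# training behaviour


def test_single_batch_overfit_and_loss_decrease(small_tileset):
    sub = TileSet(small_tileset.images[:8], small_tileset.masks[:8], small_tileset.counts[:8], [])
    net = build_model(ArchConfig(base_filters=8), seed=42)
    cfg = TrainConfig(max_epochs=60, patience=60, batch_size=8, lr=3e-3, seed=42)
    net, hist = train(net, sub, sub, cfg)
    assert hist.table["loss"].iloc[-1] < hist.table["loss"].iloc[0]
    dice, _ = _evaluate(net, sub)
    assert dice >= 0.90


def test_zero_count_weight_leaves_count_head_untrained(small_tileset):
    net = build_model(ArchConfig(base_filters=4), seed=1)
    w0 = net.fc2.W.copy()
    cfg = TrainConfig(lambda_count=0.0, max_epochs=4, patience=4, batch_size=8, seed=1)
    net, _ = train(net, small_tileset, small_tileset, cfg)
    assert np.array_equal(net.fc2.W, w0)  # no gradient reached the head
    _, mae = _evaluate(net, small_tileset)
    const_mae = np.abs(small_tileset.counts - small_tileset.counts.mean()).mean()
    assert abs(mae - const_mae) < 0.5 * const_mae + 1.0


def test_training_is_reproducible(small_tileset):
    cfg = TrainConfig(max_epochs=3, patience=3, batch_size=8, seed=9)
    _, h1 = train(build_model(seed=9), small_tileset, small_tileset, cfg)
    _, h2 = train(build_model(seed=9), small_tileset, small_tileset, cfg)
    assert h1.table.equals(h2.table)
    assert h1.best_epoch == h2.best_epoch


def test_empty_training_set_rejected(small_tileset):
    empty = TileSet(np.empty((0, 32, 32)), np.empty((0, 32, 32), bool), np.empty(0, int), [])
    with pytest.raises(ValueError):
        train(build_model(seed=0), empty, small_tileset, TrainConfig())


# ---------------------------------------------------------------------------
# prediction


def test_probability_exactly_half_is_background():
    net = build_model(ArchConfig(base_filters=4), seed=0)
    net.seg_head.W[...] = 0.0
    net.seg_head.b[...] = 0.0  # logits 0 -> probability exactly 0.5
    masks, counts = predict(net, np.zeros((1, 32, 32), dtype=np.float32))
    assert not masks.any()
    assert (counts >= 0).all()


def test_predict_is_deterministic(small_tileset):
    net = build_model(seed=2)
    m1, c1 = predict(net, small_tileset.images)
    m2, c2 = predict(net, small_tileset.images)
    assert np.array_equal(m1, m2) and np.array_equal(c1, c2)
    with pytest.raises(ValueError):
        predict(net, small_tileset.images[0])


# ---------------------------------------------------------------------------
# random search


def _tiny_sets(ts):
    return (
        TileSet(ts.images[:6], ts.masks[:6], ts.counts[:6], []),
        TileSet(ts.images[6:], ts.masks[6:], ts.counts[6:], []),
    )


def test_tune_selects_sane_learning_rate_over_decoy(small_tileset):
    space = {
        "lr": [2e-3, 50.0],  # decoy lr diverges
        "max_epochs": [3],
        "patience": [3],
        "batch_size": [6],
        "base_filters": [4],
    }
    arch, cfg, board = tune(_tiny_sets(small_tileset), space, budget=4, seed=0)
    assert cfg.lr == pytest.approx(2e-3)
    assert set(board.columns) >= {"trial", "score", "lr"}
    board2 = tune(_tiny_sets(small_tileset), space, budget=4, seed=0)[2]
    assert board.equals(board2)


def test_tune_budget_one_and_validation(small_tileset):
    sets = _tiny_sets(small_tileset)
    _, _, board = tune(sets, {"lr": [1e-3], "max_epochs": [2], "patience": [2], "batch_size": [6]}, budget=1, seed=1)
    assert len(board) == 1
    with pytest.raises(ConfigError):
        tune(sets, {}, budget=1)
    with pytest.raises(ConfigError):
        tune(sets, {"lr": [1e-3]}, budget=0)


# ---------------------------------------------------------------------------
# estimator facade


def test_estimator_fit_predict_roundtrip(small_tileset):
    est = MultitaskSpotCounter(base_filters=4, max_epochs=3, patience=3, batch_size=8, seed=0)
    est.fit(small_tileset.images, (small_tileset.masks, small_tileset.counts))
    masks, counts = est.predict(small_tileset.images)
    assert masks.shape == small_tileset.masks.shape
    assert (counts >= 0).all()
    assert est.history_.shape[0] >= 1
    assert np.isfinite(est.score(small_tileset.images, (small_tileset.masks, small_tileset.counts)))


def test_estimator_is_sklearn_compatible():
    est = MultitaskSpotCounter(lr=5e-3)
    params = est.get_params()
    assert params["lr"] == 5e-3
    est.set_params(lr=1e-3, base_filters=4)
    assert est.lr == 1e-3
    with pytest.raises(AttributeError):
        MultitaskSpotCounter().predict(np.zeros((1, 32, 32)))
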