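"""Autoencoder contracts: architecture shapes, seeded determinism, loss
descent, memorization, analytic gradients and the depth search."""

import numpy as np
import pytest

from snpclust import ArchitectureSpec, Autoencoder, depth_search, one_hot_encode
from snpclust.encoding import EncodedMatrix

from conftest import random_snp_matrix


def small_data(seed=0, n=12, L=6):
    rng = np.random.default_rng(seed)
    return one_hot_encode(random_snp_matrix(rng, n, L))


def small_spec(L=6, widths=(16, 8), bottleneck=4, **kw):
    return ArchitectureSpec(4 * L, list(widths), bottleneck, **kw)


# ------------------------------------------------------------ architecture

def test_layer_width_chain_default_spec():
    spec = ArchitectureSpec(input_dim=19248)
    assert spec.layer_widths == [19248, 2000, 700, 40, 700, 2000, 19248]


def test_spec_invariants():
    with pytest.raises(ValueError, match="bottleneck"):
        ArchitectureSpec(100, [30], bottleneck_dim=40)
    with pytest.raises(ValueError, match="bottleneck"):
        ArchitectureSpec(20, [30], bottleneck_dim=5)  # width >= input_dim
    with pytest.raises(ValueError, match="divisible by 4"):
        ArchitectureSpec(10, [8], bottleneck_dim=2)
    with pytest.raises(ValueError, match="loss"):
        ArchitectureSpec(16, [8], 2, loss="mse")


def test_build_is_seed_deterministic():
    spec = small_spec()
    a = Autoencoder.build(spec, seed=42)
    b = Autoencoder.build(spec, seed=42)
    c = Autoencoder.build(spec, seed=43)
    for wa, wb in zip(a.weights, b.weights):
        assert np.array_equal(wa, wb)
    assert any(not np.array_equal(wa, wc) for wa, wc in zip(a.weights, c.weights))
    # shape chain consistency
    widths = spec.layer_widths
    for i, W in enumerate(a.weights):
        assert W.shape == (widths[i], widths[i + 1])


# ---------------------------------------------------------------- training

def test_training_loss_decreases():
    data = small_data(n=20, L=8)
    model = Autoencoder.build(small_spec(L=8), seed=0)
    model.train(data, epochs=60, batch_size=8, seed=0)
    assert model.loss_history[-1] < model.loss_history[0]
    assert np.isfinite(model.loss_history).all()


def test_training_is_seed_deterministic():
    data = small_data()
    runs = [
        Autoencoder.build(small_spec(), seed=5).train(data, epochs=15, batch_size=4, seed=5)
        for _ in range(2)
    ]
    assert runs[0].loss_history == runs[1].loss_history
    for wa, wb in zip(runs[0].weights, runs[1].weights):
        assert np.array_equal(wa, wb)


def test_tiny_panel_memorization():
    """A 4-sample, 2-locus panel trained to convergence reconstructs its
    own calls exactly after argmax decoding."""
    from snpclust import SNPMatrix, decode_one_hot

    m = SNPMatrix(["a", "b", "c", "d"], ["l1", "l2"],
                  [["A", "T"], ["T", "G"], ["G", "C"], ["C", "A"]])
    data = one_hot_encode(m)
    spec = ArchitectureSpec(8, [6], 3, learning_rate=0.01)
    model = Autoencoder.build(spec, seed=1).train(data, epochs=500, batch_size=4, seed=1)
    rec = decode_one_hot(model.reconstruct(data))
    assert rec == m


def test_width_mismatch_and_scheme_errors():
    data = small_data()
    model = Autoencoder.build(small_spec(L=8), seed=0)
    with pytest.raises(ValueError, match="width"):
        model.train(data, epochs=1)
    lab = EncodedMatrix(np.zeros((2, 6)), "label", list("abcdef"), ["x", "y"])
    with pytest.raises(ValueError, match="one_hot"):
        Autoencoder.build(small_spec(), seed=0).train(lab, epochs=1)


def test_non_finite_loss_aborts():
    data = small_data()
    model = Autoencoder.build(small_spec(), seed=0)
    model.weights[0][:] = np.nan  # corrupt state -> training must abort loudly
    with pytest.raises(FloatingPointError, match="non-finite"):
        model.train(data, epochs=5, batch_size=4, seed=0)


# --------------------------------------------------------------- inference

def test_encode_contract():
    data = small_data(n=10)
    model = Autoencoder.build(small_spec(), seed=0)
    with pytest.raises(RuntimeError, match="train"):
        model.encode(data)
    model.train(data, epochs=5, batch_size=4, seed=0)
    emb = model.encode(data)
    assert emb.shape == (10, 4)
    # duplicated input rows map to identical embedding rows
    dup = EncodedMatrix(np.vstack([data.values[0], data.values[0]]),
                        "one_hot", data.locus_ids, ["u", "v"])
    e2 = model.encode(dup)
    assert np.array_equal(e2[0], e2[1])
    # all-zero input row still yields a finite embedding
    zero = EncodedMatrix(np.zeros((1, data.values.shape[1])),
                         "one_hot", data.locus_ids, ["z"])
    assert np.isfinite(model.encode(zero)).all()


def test_reconstruct_blocks_are_probabilities_and_loss_matches_formula():
    data = small_data(n=8)
    model = Autoencoder.build(small_spec(), seed=3)
    model.train(data, epochs=10, batch_size=4, seed=3)
    rec = model.reconstruct(data)
    n, d = rec.values.shape
    blocks = rec.values.reshape(n, d // 4, 4)
    assert np.allclose(blocks.sum(axis=2), 1.0, atol=1e-9)
    # independent evaluation of the mean per-locus cross-entropy
    y = data.values.reshape(n, d // 4, 4)
    expected = -(y * np.log(blocks + 1e-12)).sum() / (y.sum(axis=2) > 0).sum()
    assert model.reconstruction_loss(data) == pytest.approx(expected, rel=1e-12)


def test_missing_blocks_excluded_from_loss():
    vals = np.zeros((2, 8))
    vals[0, 0] = 1.0  # sample 1: locus 1 = A, locus 2 missing
    vals[1, [0, 4]] = 1.0
    data = EncodedMatrix(vals, "one_hot", ["l1", "l2"], ["a", "b"])
    model = Autoencoder.build(small_spec(L=2, widths=(6,), bottleneck=2), seed=0)
    P = model._forward(vals)[-1].reshape(2, 2, 4)
    loss = model.reconstruction_loss(data)
    expected = -(np.log(P[0, 0, 0]) + np.log(P[1, 0, 0]) + np.log(P[1, 1, 0])) / 3
    assert loss == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------- gradient

def test_analytic_gradients_match_finite_differences():
    """Central finite differences on a toy net agree with backprop to
    < 1e-5 relative error (native-implementation contract)."""
    data = small_data(n=5, L=2)
    model = Autoencoder.build(ArchitectureSpec(8, [6], 2), seed=9)
    X = np.asarray(data.values, dtype=np.float64)
    _, gW, gb = model._loss_and_grads(X)
    h = 1e-6
    rng = np.random.default_rng(0)
    for arrs, grads in ((model.weights, gW), (model.biases, gb)):
        for layer in range(len(arrs)):
            flat = arrs[layer].reshape(-1)
            for idx in rng.choice(flat.size, size=min(10, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _, _ = model._loss_and_grads(X)
                flat[idx] = orig - h
                lm, _, _ = model._loss_and_grads(X)
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = grads[layer].reshape(-1)[idx]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom < 1e-5


# ------------------------------------------------------------ depth search

def test_depth_search_report():
    data = small_data(n=10, L=4)
    base = ArchitectureSpec(16, [12, 8], 3)
    report = depth_search(data, depths=[1, 2, 3, 4], seed=2, base_spec=base,
                          epochs=8, batch_size=4)
    assert [sorted(r) for r in report] == [["depth", "final_loss", "widths"]] * 4
    losses = [r["final_loss"] for r in report]
    assert losses == sorted(losses)
    assert sorted(r["depth"] for r in report) == [1, 2, 3, 4]
    assert report == depth_search(data, depths=[1, 2, 3, 4], seed=2,
                                  base_spec=base, epochs=8, batch_size=4)

    single = depth_search(data, depths=[2], seed=2, base_spec=base, epochs=3)
    assert len(single) == 1
    with pytest.raises(ValueError, match="empty"):
        depth_search(data, depths=[], seed=2, base_spec=base)


def test_checkpoint_round_trip(tmp_path):
    data = small_data(n=6)
    model = Autoencoder.build(small_spec(), seed=4).train(data, epochs=4, batch_size=3, seed=4)
    p = tmp_path / "model.npz"
    model.save(p)
    back = Autoencoder.load(p)
    assert back.trained and back.loss_history == model.loss_history
    assert np.array_equal(back.encode(data), model.encode(data))
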