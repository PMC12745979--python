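"""Transformer correctness: gradients, memorization, sampling semantics."""

import numpy as np
import pytest

from clmprobe._nn import CoreConfig, TransformerCore
from clmprobe.model import SequenceToCompoundTransformer, cyclic_lr

TINY = dict(
    d_model=32,
    n_heads=2,
    n_encoder_layers=1,
    n_decoder_layers=1,
    d_ff=64,
    dropout=0.0,
    batch_size=4,
    random_state=0,
)


def test_gradients_match_finite_differences():
    """Analytical backward pass agrees with central finite differences on a
    sample of parameters from every layer type (float64)."""
    cfg = CoreConfig(
        d_model=8,
        n_heads=2,
        n_encoder_layers=1,
        n_decoder_layers=1,
        d_ff=16,
        dropout=0.0,
        src_vocab_size=7,
        tgt_vocab_size=9,
        max_src_len=6,
        max_tgt_len=5,
    )
    core = TransformerCore(cfg, np.random.default_rng(0))
    src = np.array([[1, 3, 4, 2, 0, 0], [1, 5, 6, 4, 2, 0]])
    tgt = np.array([[1, 4, 5, 2, 0], [1, 6, 7, 8, 2]])
    logits, cache = core.forward(src, tgt[:, :-1])
    _, dlogits = core.loss_and_dlogits(logits, tgt[:, 1:])
    grads = core.backward(dlogits, cache)

    def loss():
        lg, _ = core.forward(src, tgt[:, :-1])
        return core.loss_and_dlogits(lg, tgt[:, 1:])[0]

    eps = 1e-6
    check = np.random.default_rng(1)
    for name in (
        "src_emb",
        "tgt_emb",
        "enc0_self_Wq",
        "enc0_ffn_W1",
        "dec0_self_Wo",
        "dec0_cross_Wk",
        "dec0_ln2_g",
        "enc_final_ln_b",
        "out_W",
    ):
        p = core.params[name]
        for _ in range(3):
            idx = tuple(check.integers(s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name][idx]
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-9), name


def test_initial_loss_is_log_vocab_size():
    """With near-uniform initial outputs, per-token cross-entropy ~ ln(V)."""
    est = SequenceToCompoundTransformer(**{**TINY, "epochs": 0})
    X = ["ACDEFGHIKL", "MNPQRSTVWY", "ACDACDACDA", "MNPMNPMNPM"]
    y = ["CCO", "c1ccccc1N", "CC(=O)OC", "CBr"]
    est.fit(X, y)
    loss = est.evaluate_loss(X, y)
    V = est.tgt_vocab_.size
    assert loss == pytest.approx(np.log(V), rel=0.02)


def test_padding_contributes_zero_loss():
    cfg = CoreConfig(
        d_model=8,
        n_heads=2,
        n_encoder_layers=1,
        n_decoder_layers=1,
        d_ff=16,
        dropout=0.0,
        src_vocab_size=5,
        tgt_vocab_size=5,
        max_src_len=4,
        max_tgt_len=4,
    )
    core = TransformerCore(cfg, np.random.default_rng(0))
    logits = np.random.default_rng(2).normal(size=(1, 3, 5))
    all_pad = np.zeros((1, 3), dtype=np.int64)
    loss, dlogits = core.loss_and_dlogits(logits, all_pad)
    assert loss == 0.0
    assert np.all(dlogits == 0)


def test_memorizes_single_pair_greedy_decode():
    est = SequenceToCompoundTransformer(
        **TINY, epochs=120, base_lr=1e-3, max_lr=5e-3
    )
    X, y = ["ACDEFGHIKLMNPQRST"], ["Cc1ccccc1O"]
    est.fit(X, y)
    assert est.predict(X) == y


def test_toy_corpus_reaches_memorization_loss():
    """<= 20 pairs must reach < 0.05 loss per token within the default
    budget — guards against silent architecture bugs."""
    rng = np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    X = ["".join(rng.choice(aas, size=20)) for _ in range(20)]
    smiles = ["CCO", "CCN", "c1ccccc1", "CC(C)O", "CCCl"]
    y = [smiles[i % 5] for i in range(20)]
    est = SequenceToCompoundTransformer(
        **TINY, epochs=150, base_lr=1e-3, max_lr=4e-3
    )
    est.fit(X, y)
    assert est.loss_history_[-1] < 0.05


def test_training_is_seed_reproducible_and_input_order_invariant():
    rng = np.random.default_rng(3)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    X = ["".join(rng.choice(aas, size=12)) for _ in range(8)]
    y = ["CCO", "CCN", "CCC", "CCCl", "CCBr", "CC=C", "C#N", "CCOC"]
    a = SequenceToCompoundTransformer(**TINY, epochs=5).fit(X, y)
    b = SequenceToCompoundTransformer(**TINY, epochs=5).fit(X, y)
    order = [3, 1, 4, 0, 5, 2, 7, 6]
    c = SequenceToCompoundTransformer(**TINY, epochs=5).fit(
        [X[i] for i in order], [y[i] for i in order]
    )
    for key in a.core_.params:
        np.testing.assert_array_equal(a.core_.params[key], b.core_.params[key])
        np.testing.assert_array_equal(a.core_.params[key], c.core_.params[key])


def test_low_temperature_limit_equals_greedy():
    est = SequenceToCompoundTransformer(**TINY, epochs=40, base_lr=1e-3, max_lr=4e-3)
    X, y = ["ACDEFGHIKLMNPQRST", "MNPQRSTVWYACDEFGH"], ["CCO", "CCN"]
    est.fit(X, y)
    greedy = est.predict([X[0]])[0]
    cold = est.sample_strings(X[0], 5, temperature=1e-6, seed=0)
    assert all(s == greedy for s in cold)


def test_sampling_seed_reproducible():
    est = SequenceToCompoundTransformer(**TINY, epochs=10).fit(
        ["ACDEFGHIKL"], ["CCO"]
    )
    a = est.sample_strings("ACDEFGHIKL", 20, seed=9)
    b = est.sample_strings("ACDEFGHIKL", 20, seed=9)
    assert a == b


def test_nonpositive_temperature_rejected():
    est = SequenceToCompoundTransformer(**TINY, epochs=1).fit(["ACDEF"], ["CCO"])
    with pytest.raises(ValueError):
        est.sample_strings("ACDEF", 2, temperature=0.0)


def test_sampling_frequencies_match_softmax_on_fixed_logits():
    """A single-step model with output logits forced to (2, 1, 0) over three
    content tokens samples them with closed-form softmax probabilities
    (0.665, 0.245, 0.090) within 3 standard errors."""
    est = SequenceToCompoundTransformer(**TINY, epochs=0)
    est.fit(["ACDEF"], ["CNO"])  # vocab: specials + C, N, O
    core = est.core_
    core.params["out_W"][:] = 0.0
    bias = np.full(core.config.tgt_vocab_size, -1e9)
    idx = [est.tgt_vocab_.index[t] for t in ("C", "N", "O")]
    for i, logit in zip(idx, (2.0, 1.0, 0.0)):
        bias[i] = logit
    core.params["out_b"][:] = bias
    n = 10_000
    strings = est.sample_strings("ACDEF", n, temperature=1.0, seed=0)
    firsts = [s[0] for s in strings if s]
    probs = np.exp([2.0, 1.0, 0.0]) / np.exp([2.0, 1.0, 0.0]).sum()
    for token, p in zip("CNO", probs):
        freq = firsts.count(token) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) <= 3 * se


@pytest.fixture(scope="module")
def parent():
    rng = np.random.default_rng(1)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    X = ["".join(rng.choice(aas, size=12)) for _ in range(6)]
    y = ["CCO", "CCN", "CCC", "CCCl", "CCBr", "CCOC"]
    est = SequenceToCompoundTransformer(**TINY, epochs=5).fit(X, y)
    return est, X, y


class TestFinetune:
    def test_leakage_error_for_foreign_pairs(self, parent):
        est, X, y = parent
        with pytest.raises(ValueError, match="not part of the"):
            est.finetune(["WWWWWWWWWWWW"], ["CCO"])

    def test_empty_family_set_rejected(self, parent):
        est, _, _ = parent
        with pytest.raises(ValueError):
            est.finetune([], [])

    def test_provenance_chains_to_parent(self, parent):
        est, X, y = parent
        child = est.finetune(X[:2], y[:2], epochs=2)
        assert child.provenance_["parent_hash"] == est.provenance_["dataset_hash"]
        # parent parameters untouched by child training
        assert est.provenance_["parent_hash"] is None

    def test_parent_parameters_left_intact(self, parent):
        est, X, y = parent
        before = {k: v.copy() for k, v in est.core_.params.items()}
        est.finetune(X[:3], y[:3], epochs=2)
        for k in before:
            np.testing.assert_array_equal(before[k], est.core_.params[k])


def test_checkpoint_round_trip(tmp_path):
    est = SequenceToCompoundTransformer(**TINY, epochs=30, base_lr=1e-3, max_lr=4e-3)
    X, y = ["ACDEFGHIKLMNPQRST"], ["CCO"]
    est.fit(X, y)
    est.save(tmp_path / "model")
    back = SequenceToCompoundTransformer.load(tmp_path / "model")
    assert back.predict(X) == est.predict(X)
    assert back.tgt_vocab_ == est.tgt_vocab_


def test_cyclic_lr_triangular_shape():
    half = 10
    lrs = [cyclic_lr(t, 1e-4, 1e-3, half) for t in range(41)]
    assert lrs[0] == pytest.approx(1e-4)
    assert lrs[10] == pytest.approx(1e-3)
    assert lrs[20] == pytest.approx(1e-4)
    assert lrs[30] == pytest.approx(1e-3)
    assert max(lrs) <= 1e-3 and min(lrs) >= 1e-4
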