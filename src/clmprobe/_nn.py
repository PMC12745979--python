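"""NumPy encoder-decoder transformer with manual backpropagation.

A compact, CPU-oriented implementation of the original encoder-decoder
transformer (pre-norm variant for optimizer-friendly training): learned token
embeddings scaled by sqrt(d) plus fixed sinusoidal positional encodings,
multi-head scaled dot-product attention, position-wise feed-forward blocks
with ReLU, residual connections and layer normalization, and a linear output
projection trained with padding-masked cross-entropy.

Every layer exposes an explicit forward (returning a cache) and backward
(consuming it); gradients are exact and verified against finite differences
in the test suite. Sampling uses per-layer key/value caches so that
autoregressive decoding is O(T) attention work per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import positional_encoding

_NEG = -1e9  # additive mask value (finite to avoid NaN in softmax)


# ---------------------------------------------------------------------------
# primitive layers: forward returns (out, cache); backward consumes cache
# ---------------------------------------------------------------------------


def linear_fwd(x, W, b):
    return x @ W + b, (x, W)


def linear_bwd(dy, cache):
    x, W = cache
    dx = dy @ W.T
    dW = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    return dx, dW, db


def layernorm_fwd(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    return gamma * xhat + beta, (xhat, inv_std, gamma)


def layernorm_bwd(dy, cache):
    xhat, inv_std, gamma = cache
    n = xhat.shape[-1]
    dgamma = (dy * xhat).reshape(-1, n).sum(axis=0)
    dbeta = dy.reshape(-1, n).sum(axis=0)
    dxhat = dy * gamma
    dx = (
        inv_std
        / n
        * (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
    )
    return dx, dgamma, dbeta


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dropout_fwd(x, rate, rng):
    if rate <= 0.0 or rng is None:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def dropout_bwd(dy, mask):
    return dy if mask is None else dy * mask


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


def attention_fwd(xq, xk, xv, p, prefix, n_heads, mask=None):
    """Multi-head scaled dot-product attention.

    ``mask`` is additive, broadcastable to (B, 1, Tq, Tk) with ``_NEG`` at
    disallowed positions. Parameter names are ``{prefix}_{Wq,bq,...}``.
    """
    q, cq = linear_fwd(xq, p[f"{prefix}_Wq"], p[f"{prefix}_bq"])
    k, ck = linear_fwd(xk, p[f"{prefix}_Wk"], p[f"{prefix}_bk"])
    v, cv = linear_fwd(xv, p[f"{prefix}_Wv"], p[f"{prefix}_bv"])
    qh, kh, vh = (_split_heads(z, n_heads) for z in (q, k, v))
    scale = 1.0 / np.sqrt(qh.shape[-1])
    scores = qh @ kh.transpose(0, 1, 3, 2) * scale
    if mask is not None:
        scores = scores + mask
    attn = softmax(scores)
    ctx = attn @ vh
    merged = _merge_heads(ctx)
    out, co = linear_fwd(merged, p[f"{prefix}_Wo"], p[f"{prefix}_bo"])
    return out, (cq, ck, cv, qh, kh, vh, attn, merged, co, scale, n_heads)


def attention_bwd(dy, cache, grads, prefix):
    cq, ck, cv, qh, kh, vh, attn, merged, co, scale, n_heads = cache
    dmerged, dWo, dbo = linear_bwd(dy, co)
    grads[f"{prefix}_Wo"] += dWo
    grads[f"{prefix}_bo"] += dbo
    dctx = _split_heads(dmerged, n_heads)
    dattn = dctx @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ dctx
    dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    dqh = dscores @ kh * scale
    dkh = dscores.transpose(0, 1, 3, 2) @ qh * scale
    dxq, dWq, dbq = linear_bwd(_merge_heads(dqh), cq)
    dxk, dWk, dbk = linear_bwd(_merge_heads(dkh), ck)
    dxv, dWv, dbv = linear_bwd(_merge_heads(dvh), cv)
    grads[f"{prefix}_Wq"] += dWq
    grads[f"{prefix}_bq"] += dbq
    grads[f"{prefix}_Wk"] += dWk
    grads[f"{prefix}_bk"] += dbk
    grads[f"{prefix}_Wv"] += dWv
    grads[f"{prefix}_bv"] += dbv
    return dxq, dxk, dxv


def ffn_fwd(x, p, prefix):
    h, c1 = linear_fwd(x, p[f"{prefix}_W1"], p[f"{prefix}_b1"])
    relu_mask = h > 0
    out, c2 = linear_fwd(h * relu_mask, p[f"{prefix}_W2"], p[f"{prefix}_b2"])
    return out, (c1, relu_mask, c2)


def ffn_bwd(dy, cache, grads, prefix):
    c1, relu_mask, c2 = cache
    dh, dW2, db2 = linear_bwd(dy, c2)
    grads[f"{prefix}_W2"] += dW2
    grads[f"{prefix}_b2"] += db2
    dh = dh * relu_mask
    dx, dW1, db1 = linear_bwd(dh, c1)
    grads[f"{prefix}_W1"] += dW1
    grads[f"{prefix}_b1"] += db1
    return dx


# ---------------------------------------------------------------------------
# transformer core
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoreConfig:
    d_model: int
    n_heads: int
    n_encoder_layers: int
    n_decoder_layers: int
    d_ff: int
    dropout: float
    src_vocab_size: int
    tgt_vocab_size: int
    max_src_len: int
    max_tgt_len: int
    pad_id: int = 0
    dtype: str = "float64"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even (sinusoidal encoding)")
        for name in (
            "d_model",
            "n_heads",
            "n_encoder_layers",
            "n_decoder_layers",
            "d_ff",
            "src_vocab_size",
            "tgt_vocab_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class TransformerCore:
    """Parameters + forward/backward/sampling for one model instance."""

    def __init__(self, config: CoreConfig, rng: np.random.Generator):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng)
        d = config.d_model
        self._pe_src = positional_encoding(
            np.arange(config.max_src_len), d
        ).astype(self.dtype)
        self._pe_tgt = positional_encoding(
            np.arange(config.max_tgt_len), d
        ).astype(self.dtype)

    # ---- parameter initialization ---------------------------------------

    def _glorot(self, rng, shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape).astype(self.dtype)

    def _init_params(self, rng):
        c = self.config
        p = self.params
        d, ff = c.d_model, c.d_ff
        p["src_emb"] = (rng.standard_normal((c.src_vocab_size, d)) * d**-0.5).astype(
            self.dtype
        )
        p["tgt_emb"] = (rng.standard_normal((c.tgt_vocab_size, d)) * d**-0.5).astype(
            self.dtype
        )

        def attn_block(prefix):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{prefix}_{name}"] = self._glorot(rng, (d, d))
            for name in ("bq", "bk", "bv", "bo"):
                p[f"{prefix}_{name}"] = np.zeros(d, dtype=self.dtype)

        def ln_block(prefix):
            p[f"{prefix}_g"] = np.ones(d, dtype=self.dtype)
            p[f"{prefix}_b"] = np.zeros(d, dtype=self.dtype)

        def ffn_block(prefix):
            p[f"{prefix}_W1"] = self._glorot(rng, (d, ff))
            p[f"{prefix}_b1"] = np.zeros(ff, dtype=self.dtype)
            p[f"{prefix}_W2"] = self._glorot(rng, (ff, d))
            p[f"{prefix}_b2"] = np.zeros(d, dtype=self.dtype)

        for i in range(c.n_encoder_layers):
            attn_block(f"enc{i}_self")
            ffn_block(f"enc{i}_ffn")
            ln_block(f"enc{i}_ln1")
            ln_block(f"enc{i}_ln2")
        ln_block("enc_final_ln")
        for i in range(c.n_decoder_layers):
            attn_block(f"dec{i}_self")
            attn_block(f"dec{i}_cross")
            ffn_block(f"dec{i}_ffn")
            ln_block(f"dec{i}_ln1")
            ln_block(f"dec{i}_ln2")
            ln_block(f"dec{i}_ln3")
        ln_block("dec_final_ln")
        # small output projection: initial token distribution is near-uniform
        # (per-token loss ~ ln V) without zeroing upstream gradient flow
        p["out_W"] = self._glorot(rng, (d, c.tgt_vocab_size)) * 0.05
        p["out_b"] = np.zeros(c.tgt_vocab_size, dtype=self.dtype)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # ---- masks -----------------------------------------------------------

    def _src_mask(self, src_ids):
        # (B, 1, 1, S): block attention to padding keys
        return np.where(
            src_ids[:, None, None, :] == self.config.pad_id, _NEG, 0.0
        ).astype(self.dtype)

    def _causal_mask(self, t):
        return np.triu(np.full((1, 1, t, t), _NEG, dtype=self.dtype), k=1)

    # ---- forward / backward ----------------------------------------------

    def forward(self, src_ids, tgt_in_ids, train=False, rng=None):
        """Teacher-forced forward pass; returns (logits, cache)."""
        c, p = self.config, self.params
        drop = c.dropout if train else 0.0
        cache: dict = {"drops": []}

        def drop_fwd(x):
            out, mask = dropout_fwd(x, drop, rng)
            cache["drops"].append(mask)
            return out

        src_mask = self._src_mask(src_ids)
        causal = self._causal_mask(tgt_in_ids.shape[1])

        x = p["src_emb"][src_ids] * np.sqrt(c.d_model) + self._pe_src[: src_ids.shape[1]]
        x = drop_fwd(x)
        enc_caches = []
        for i in range(c.n_encoder_layers):
            h, c_ln1 = layernorm_fwd(x, p[f"enc{i}_ln1_g"], p[f"enc{i}_ln1_b"])
            a, c_attn = attention_fwd(h, h, h, p, f"enc{i}_self", c.n_heads, src_mask)
            x = x + drop_fwd(a)
            h2, c_ln2 = layernorm_fwd(x, p[f"enc{i}_ln2_g"], p[f"enc{i}_ln2_b"])
            f, c_ffn = ffn_fwd(h2, p, f"enc{i}_ffn")
            x = x + drop_fwd(f)
            enc_caches.append((c_ln1, c_attn, c_ln2, c_ffn))
        memory, c_encln = layernorm_fwd(x, p["enc_final_ln_g"], p["enc_final_ln_b"])

        y = (
            p["tgt_emb"][tgt_in_ids] * np.sqrt(c.d_model)
            + self._pe_tgt[: tgt_in_ids.shape[1]]
        )
        y = drop_fwd(y)
        dec_caches = []
        for i in range(c.n_decoder_layers):
            h, c_ln1 = layernorm_fwd(y, p[f"dec{i}_ln1_g"], p[f"dec{i}_ln1_b"])
            a, c_self = attention_fwd(h, h, h, p, f"dec{i}_self", c.n_heads, causal)
            y = y + drop_fwd(a)
            h2, c_ln2 = layernorm_fwd(y, p[f"dec{i}_ln2_g"], p[f"dec{i}_ln2_b"])
            a2, c_cross = attention_fwd(
                h2, memory, memory, p, f"dec{i}_cross", c.n_heads, src_mask
            )
            y = y + drop_fwd(a2)
            h3, c_ln3 = layernorm_fwd(y, p[f"dec{i}_ln3_g"], p[f"dec{i}_ln3_b"])
            f, c_ffn = ffn_fwd(h3, p, f"dec{i}_ffn")
            y = y + drop_fwd(f)
            dec_caches.append((c_ln1, c_self, c_ln2, c_cross, c_ln3, c_ffn))
        yf, c_decln = layernorm_fwd(y, p["dec_final_ln_g"], p["dec_final_ln_b"])
        logits, c_out = linear_fwd(yf, p["out_W"], p["out_b"])

        cache.update(
            src_ids=src_ids,
            tgt_in_ids=tgt_in_ids,
            enc_caches=enc_caches,
            dec_caches=dec_caches,
            c_encln=c_encln,
            c_decln=c_decln,
            c_out=c_out,
        )
        return logits, cache

    def backward(self, dlogits, cache):
        """Gradients of all parameters given d(loss)/d(logits)."""
        c, p = self.config, self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        drops = cache["drops"]
        drop_idx = len(drops)  # consume in reverse

        def drop_bwd(dy):
            nonlocal drop_idx
            drop_idx -= 1
            return dropout_bwd(dy, drops[drop_idx])

        dyf, dWout, dbout = linear_bwd(dlogits, cache["c_out"])
        grads["out_W"] += dWout
        grads["out_b"] += dbout
        dy, dg, db = layernorm_bwd(dyf, cache["c_decln"])
        grads["dec_final_ln_g"] += dg
        grads["dec_final_ln_b"] += db

        dmemory = None
        for i in reversed(range(c.n_decoder_layers)):
            c_ln1, c_self, c_ln2, c_cross, c_ln3, c_ffn = cache["dec_caches"][i]
            df = drop_bwd(dy)
            dh3 = ffn_bwd(df, c_ffn, grads, f"dec{i}_ffn")
            dy2, dg, db = layernorm_bwd(dh3, c_ln3)
            grads[f"dec{i}_ln3_g"] += dg
            grads[f"dec{i}_ln3_b"] += db
            dy = dy + dy2
            da2 = drop_bwd(dy)
            dh2, dmem_k, dmem_v = attention_bwd(da2, c_cross, grads, f"dec{i}_cross")
            dmem = dmem_k + dmem_v
            dmemory = dmem if dmemory is None else dmemory + dmem
            dy2, dg, db = layernorm_bwd(dh2, c_ln2)
            grads[f"dec{i}_ln2_g"] += dg
            grads[f"dec{i}_ln2_b"] += db
            dy = dy + dy2
            da = drop_bwd(dy)
            dq, dk, dv = attention_bwd(da, c_self, grads, f"dec{i}_self")
            dh = dq + dk + dv
            dy2, dg, db = layernorm_bwd(dh, c_ln1)
            grads[f"dec{i}_ln1_g"] += dg
            grads[f"dec{i}_ln1_b"] += db
            dy = dy + dy2
        dy = drop_bwd(dy)
        np.add.at(
            grads["tgt_emb"], cache["tgt_in_ids"], dy * np.sqrt(c.d_model)
        )

        dx, dg, db = layernorm_bwd(dmemory, cache["c_encln"])
        grads["enc_final_ln_g"] += dg
        grads["enc_final_ln_b"] += db
        for i in reversed(range(c.n_encoder_layers)):
            c_ln1, c_attn, c_ln2, c_ffn = cache["enc_caches"][i]
            df = drop_bwd(dx)
            dh2 = ffn_bwd(df, c_ffn, grads, f"enc{i}_ffn")
            dx2, dg, db = layernorm_bwd(dh2, c_ln2)
            grads[f"enc{i}_ln2_g"] += dg
            grads[f"enc{i}_ln2_b"] += db
            dx = dx + dx2
            da = drop_bwd(dx)
            dq, dk, dv = attention_bwd(da, c_attn, grads, f"enc{i}_self")
            dh = dq + dk + dv
            dx2, dg, db = layernorm_bwd(dh, c_ln1)
            grads[f"enc{i}_ln1_g"] += dg
            grads[f"enc{i}_ln1_b"] += db
            dx = dx + dx2
        dx = drop_bwd(dx)
        np.add.at(grads["src_emb"], cache["src_ids"], dx * np.sqrt(c.d_model))
        return grads

    # ---- loss ------------------------------------------------------------

    def loss_and_dlogits(self, logits, labels):
        """Padding-masked mean cross-entropy per token and its gradient."""
        probs = softmax(logits)
        mask = labels != self.config.pad_id
        n = max(int(mask.sum()), 1)
        picked = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
        loss = float(-(np.log(np.maximum(picked, 1e-300)) * mask).sum() / n)
        dlogits = probs.copy()
        b, t = labels.shape
        dlogits[np.arange(b)[:, None], np.arange(t)[None, :], labels] -= 1.0
        dlogits *= mask[..., None] / n
        return loss, dlogits.astype(self.dtype)

    # ---- inference -------------------------------------------------------

    def encode(self, src_ids):
        """Encoder stack only (eval mode); returns (memory, src_mask)."""
        c, p = self.config, self.params
        src_mask = self._src_mask(src_ids)
        x = p["src_emb"][src_ids] * np.sqrt(c.d_model) + self._pe_src[: src_ids.shape[1]]
        for i in range(c.n_encoder_layers):
            h, _ = layernorm_fwd(x, p[f"enc{i}_ln1_g"], p[f"enc{i}_ln1_b"])
            a, _ = attention_fwd(h, h, h, p, f"enc{i}_self", c.n_heads, src_mask)
            x = x + a
            h2, _ = layernorm_fwd(x, p[f"enc{i}_ln2_g"], p[f"enc{i}_ln2_b"])
            f, _ = ffn_fwd(h2, p, f"enc{i}_ffn")
            x = x + f
        memory, _ = layernorm_fwd(x, p["enc_final_ln_g"], p["enc_final_ln_b"])
        return memory, src_mask

    def generate(
        self,
        src_ids,
        start_id,
        end_id,
        max_len,
        temperature=1.0,
        rng=None,
        n_samples=1,
    ):
        """Autoregressive decoding of one source with per-layer K/V caches.

        ``src_ids`` is a single encoded source of shape (S,); ``n_samples``
        strings are decoded in one batch. ``rng=None`` selects greedy argmax
        decoding, otherwise multinomial sampling with logits divided by
        ``temperature``.
        """
        memory, src_mask = self.encode(src_ids[None, :])
        return self._decode_batch(
            np.broadcast_to(memory, (n_samples,) + memory.shape[1:]),
            np.broadcast_to(src_mask, (n_samples,) + src_mask.shape[1:]),
            start_id,
            end_id,
            max_len,
            temperature,
            rng,
        )

    def generate_many(
        self,
        src_ids,
        counts,
        start_id,
        end_id,
        max_len,
        temperature=1.0,
        rng=None,
    ):
        """Decode several sources in one batch: ``counts[i]`` samples for row i.

        Encoding runs once per unique source; the decoder processes all
        samples simultaneously. Returns one token-list per sample, grouped
        per source in order.
        """
        memory, src_mask = self.encode(src_ids)
        memory = np.repeat(memory, counts, axis=0)
        src_mask = np.repeat(src_mask, counts, axis=0)
        flat = self._decode_batch(
            memory, src_mask, start_id, end_id, max_len, temperature, rng
        )
        out, offset = [], 0
        for n in counts:
            out.append(flat[offset : offset + n])
            offset += n
        return out

    def _decode_batch(
        self, memory, src_mask, start_id, end_id, max_len, temperature, rng
    ):
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        c, p = self.config, self.params
        b = memory.shape[0]

        # cross-attention keys/values are fixed per layer
        cross_kv = []
        for i in range(c.n_decoder_layers):
            k = _split_heads(
                memory @ p[f"dec{i}_cross_Wk"] + p[f"dec{i}_cross_bk"], c.n_heads
            )
            v = _split_heads(
                memory @ p[f"dec{i}_cross_Wv"] + p[f"dec{i}_cross_bv"], c.n_heads
            )
            cross_kv.append((k, v))

        self_k = [None] * c.n_decoder_layers
        self_v = [None] * c.n_decoder_layers
        last = np.full(b, start_id, dtype=np.int64)
        finished = np.zeros(b, dtype=bool)
        out_tokens: list[list[int]] = [[] for _ in range(b)]
        orig_idx = np.arange(b)
        scale = 1.0 / np.sqrt(c.d_model // c.n_heads)

        for t in range(max_len - 1):
            y = p["tgt_emb"][last[:, None]] * np.sqrt(c.d_model) + self._pe_tgt[t]
            for i in range(c.n_decoder_layers):
                h, _ = layernorm_fwd(y, p[f"dec{i}_ln1_g"], p[f"dec{i}_ln1_b"])
                q = _split_heads(h @ p[f"dec{i}_self_Wq"] + p[f"dec{i}_self_bq"], c.n_heads)
                k = _split_heads(h @ p[f"dec{i}_self_Wk"] + p[f"dec{i}_self_bk"], c.n_heads)
                v = _split_heads(h @ p[f"dec{i}_self_Wv"] + p[f"dec{i}_self_bv"], c.n_heads)
                self_k[i] = k if self_k[i] is None else np.concatenate([self_k[i], k], axis=2)
                self_v[i] = v if self_v[i] is None else np.concatenate([self_v[i], v], axis=2)
                attn = softmax(q @ self_k[i].transpose(0, 1, 3, 2) * scale)
                a = _merge_heads(attn @ self_v[i]) @ p[f"dec{i}_self_Wo"] + p[f"dec{i}_self_bo"]
                y = y + a
                h2, _ = layernorm_fwd(y, p[f"dec{i}_ln2_g"], p[f"dec{i}_ln2_b"])
                q2 = _split_heads(
                    h2 @ p[f"dec{i}_cross_Wq"] + p[f"dec{i}_cross_bq"], c.n_heads
                )
                ck, cv = cross_kv[i]
                scores = q2 @ ck.transpose(0, 1, 3, 2) * scale + src_mask
                a2 = _merge_heads(softmax(scores) @ cv) @ p[f"dec{i}_cross_Wo"] + p[
                    f"dec{i}_cross_bo"
                ]
                y = y + a2
                h3, _ = layernorm_fwd(y, p[f"dec{i}_ln3_g"], p[f"dec{i}_ln3_b"])
                f, _ = ffn_fwd(h3, p, f"dec{i}_ffn")
                y = y + f
            yf, _ = layernorm_fwd(y, p["dec_final_ln_g"], p["dec_final_ln_b"])
            logits = (yf[:, 0] @ p["out_W"] + p["out_b"]) / temperature
            n_active = logits.shape[0]
            if rng is None:
                next_ids = logits.argmax(axis=-1)
            else:
                probs = softmax(logits)
                u = rng.random((n_active, 1))
                next_ids = (probs.cumsum(axis=-1) > u).argmax(axis=-1)
            emit = ~finished & (next_ids != end_id) & (next_ids != self.config.pad_id)
            for j in np.nonzero(emit)[0]:
                out_tokens[orig_idx[j]].append(int(next_ids[j]))
            finished |= next_ids == end_id
            if finished.all():
                break
            # compact: drop finished rows from the batch and all caches so
            # stragglers do not pay for the whole batch
            if finished.sum() >= max(64, n_active // 3):
                keep = ~finished
                last = next_ids[keep]
                orig_idx = orig_idx[keep]
                finished = np.zeros(last.shape[0], dtype=bool)
                src_mask = src_mask[keep]
                cross_kv = [(k[keep], v[keep]) for k, v in cross_kv]
                self_k = [k[keep] for k in self_k]
                self_v = [v[keep] for v in self_v]
            else:
                last = next_ids
        return out_tokens
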