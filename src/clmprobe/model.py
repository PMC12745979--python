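"""Sequence-to-compound transformer as a scikit-learn style estimator.

``SequenceToCompoundTransformer.fit(X, y)`` trains an encoder-decoder
transformer to translate protein residue strings (encoder input) into SMILES
strings (decoder output) with teacher-forced, padding-masked cross-entropy.
Vocabularies are corpus-derived at ``fit`` time and frozen; fine-tuning on a
subset of the training pairs (e.g. one protein family) reuses the parent's
vocabularies and parameters and chains provenance.

Training uses Adam with a triangular cyclic learning-rate schedule and is
bit-reproducible given ``random_state``: shuffling, initialization, dropout
and sampling all derive from it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import CoreConfig, TransformerCore
from .encoding import (
    TokenVocabulary,
    encode_protein,
    encode_smiles,
    tokenize_protein,
    tokenize_smiles,
)


def _pair_hash(sequence: str, smiles: str) -> str:
    return hashlib.sha256(f"{sequence}\t{smiles}".encode()).hexdigest()[:16]


def cyclic_lr(step: int, base_lr: float, max_lr: float, half_cycle_steps: int) -> float:
    """Triangular cyclic learning rate (linear up then down each cycle)."""
    cycle = np.floor(1 + step / (2 * half_cycle_steps))
    x = abs(step / half_cycle_steps - 2 * cycle + 1)
    return base_lr + (max_lr - base_lr) * max(0.0, 1.0 - x)


class SequenceToCompoundTransformer(BaseEstimator):
    """Encoder-decoder transformer mapping protein sequences to SMILES.

    Parameters follow the scaled-down desk configuration: the smallest model
    that reliably memorizes synthetic corpora on a single CPU. All are
    overridable in the usual sklearn way.

    Attributes (after fit)
    ----------------------
    core_ : TransformerCore
        Parameters and forward/backward machinery.
    src_vocab_, tgt_vocab_ : TokenVocabulary
        Frozen residue / SMILES vocabularies.
    loss_history_ : list of float
        Per-epoch mean training loss (per token).
    val_loss_history_ : list of float
        Per-epoch held-out loss (empty if validation_fraction=0).
    provenance_ : dict
        Dataset manifest hash, train config, optional parent-model hash.
    """

    def __init__(
        self,
        d_model: int = 64,
        n_heads: int = 4,
        n_encoder_layers: int = 2,
        n_decoder_layers: int = 2,
        d_ff: int = 128,
        dropout: float = 0.1,
        batch_size: int = 32,
        epochs: int = 60,
        base_lr: float = 1e-4,
        max_lr: float = 1e-3,
        cycle_epochs: int = 4,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        adam_eps: float = 1e-8,
        validation_fraction: float = 0.0,
        patience: int | None = None,
        permissive_residues: bool = False,
        dtype: str = "float64",
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_encoder_layers = n_encoder_layers
        self.n_decoder_layers = n_decoder_layers
        self.d_ff = d_ff
        self.dropout = dropout
        self.batch_size = batch_size
        self.epochs = epochs
        self.base_lr = base_lr
        self.max_lr = max_lr
        self.cycle_epochs = cycle_epochs
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.permissive_residues = permissive_residues
        self.dtype = dtype
        self.random_state = random_state
        self.verbose = verbose

    # ---- encoding helpers ------------------------------------------------

    def _encode_dataset(self, X, y):
        src = np.stack(
            [
                encode_protein(s, self.src_vocab_, self.permissive_residues)
                for s in X
            ]
        )
        tgt = np.stack([encode_smiles(s, self.tgt_vocab_) for s in y])
        return src, tgt

    def _validate_xy(self, X, y):
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if len(X) == 0:
            raise ValueError("cannot train on an empty pair set")

    # ---- fitting ---------------------------------------------------------

    def fit(self, X, y, _parent=None):
        """Train on sequence-compound pairs.

        X : list of residue strings (encoder side)
        y : list of SMILES strings (decoder side)
        """
        self._validate_xy(X, y)
        if self.base_lr > self.max_lr:
            raise ValueError("base_lr must not exceed max_lr")
        # canonical pair order: training depends only on the pair *set* and
        # the seed, never on the caller's ordering
        order = sorted(range(len(X)), key=lambda i: (X[i], y[i]))
        X = [X[i] for i in order]
        y = [y[i] for i in order]

        if _parent is None:
            self.src_vocab_ = TokenVocabulary.from_token_lists(
                [tokenize_protein(s, self.permissive_residues) for s in X]
            )
            self.tgt_vocab_ = TokenVocabulary.from_token_lists(
                [tokenize_smiles(s) for s in y]
            )
        else:
            check_is_fitted(_parent)
            self.src_vocab_ = _parent.src_vocab_
            self.tgt_vocab_ = _parent.tgt_vocab_

        config = CoreConfig(
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_encoder_layers=self.n_encoder_layers,
            n_decoder_layers=self.n_decoder_layers,
            d_ff=self.d_ff,
            dropout=self.dropout,
            src_vocab_size=self.src_vocab_.size,
            tgt_vocab_size=self.tgt_vocab_.size,
            max_src_len=self.src_vocab_.max_length,
            max_tgt_len=self.tgt_vocab_.max_length,
            dtype=self.dtype,
        )
        rng = np.random.default_rng(self.random_state)
        self.core_ = TransformerCore(config, rng)
        if _parent is not None:
            if _parent.core_.config != config:
                raise ValueError("fine-tuning requires an identical architecture")
            self.core_.params = {k: v.copy() for k, v in _parent.core_.params.items()}

        src, tgt = self._encode_dataset(X, y)
        n = len(X)
        n_val = int(round(self.validation_fraction * n))
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            raise ValueError("validation split leaves no training pairs")

        self.loss_history_, self.val_loss_history_ = [], []
        self._train(src, tgt, train_idx, val_idx, rng)

        pair_hashes = sorted(_pair_hash(a, b) for a, b in zip(X, y))
        self.provenance_ = {
            "n_pairs": n,
            "dataset_hash": hashlib.sha256("".join(pair_hashes).encode()).hexdigest(),
            "pair_hashes": pair_hashes,
            "train_config": {
                k: v for k, v in self.get_params().items() if not callable(v)
            },
            "parent_hash": None
            if _parent is None
            else _parent.provenance_["dataset_hash"],
            "loss_trajectory": list(self.loss_history_),
        }
        return self

    def _train(self, src, tgt, train_idx, val_idx, rng):
        core = self.core_
        params = core.params
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        steps_per_epoch = max(1, int(np.ceil(len(train_idx) / self.batch_size)))
        half_cycle = max(1, self.cycle_epochs * steps_per_epoch // 2)
        step = 0
        best_val, best_params, stale = np.inf, None, 0
        for epoch in range(self.epochs):
            perm = train_idx[rng.permutation(len(train_idx))]
            epoch_loss, epoch_tokens = 0.0, 0
            for start in range(0, len(perm), self.batch_size):
                batch = perm[start : start + self.batch_size]
                sb, tb = src[batch], tgt[batch]
                logits, cache = core.forward(sb, tb[:, :-1], train=True, rng=rng)
                loss, dlogits = core.loss_and_dlogits(logits, tb[:, 1:])
                grads = core.backward(dlogits, cache)
                lr = cyclic_lr(step, self.base_lr, self.max_lr, half_cycle)
                step += 1
                b1, b2 = self.adam_beta1, self.adam_beta2
                for key, g in grads.items():
                    m[key] = b1 * m[key] + (1 - b1) * g
                    v[key] = b2 * v[key] + (1 - b2) * g * g
                    mhat = m[key] / (1 - b1**step)
                    vhat = v[key] / (1 - b2**step)
                    params[key] -= lr * mhat / (np.sqrt(vhat) + self.adam_eps)
                ntok = int((tb[:, 1:] != core.config.pad_id).sum())
                epoch_loss += loss * ntok
                epoch_tokens += ntok
            self.loss_history_.append(epoch_loss / max(epoch_tokens, 1))
            if len(val_idx):
                val_loss = self._dataset_loss(src[val_idx], tgt[val_idx])
                self.val_loss_history_.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                    if self.patience is not None:
                        best_params = {k: p.copy() for k, p in params.items()}
                else:
                    stale += 1
                    if self.patience is not None and stale > self.patience:
                        break
            if self.verbose:
                msg = f"epoch {epoch + 1}: loss/token {self.loss_history_[-1]:.4f}"
                if self.val_loss_history_:
                    msg += f" val {self.val_loss_history_[-1]:.4f}"
                print(msg)
        if best_params is not None:
            core.params = best_params

    def _dataset_loss(self, src, tgt):
        total, tokens = 0.0, 0
        for start in range(0, len(src), self.batch_size):
            sb, tb = src[start : start + self.batch_size], tgt[start : start + self.batch_size]
            logits, _ = self.core_.forward(sb, tb[:, :-1], train=False)
            loss, _ = self.core_.loss_and_dlogits(logits, tb[:, 1:])
            ntok = int((tb[:, 1:] != self.core_.config.pad_id).sum())
            total += loss * ntok
            tokens += ntok
        return total / max(tokens, 1)

    def evaluate_loss(self, X, y) -> float:
        """Mean per-token cross-entropy of (X, y) under the fitted model."""
        check_is_fitted(self)
        src, tgt = self._encode_dataset(X, y)
        return self._dataset_loss(src, tgt)

    # ---- fine-tuning -----------------------------------------------------

    def finetune(self, X, y, **overrides) -> "SequenceToCompoundTransformer":
        """Continue training on a subset of the parent's training pairs.

        Returns a *new* fitted estimator; the parent is left intact. Pairs
        outside the parent's training set raise a leakage error.
        """
        check_is_fitted(self)
        self._validate_xy(X, y)
        parent_hashes = set(self.provenance_["pair_hashes"])
        leaked = [
            i
            for i, (a, b) in enumerate(zip(X, y))
            if _pair_hash(a, b) not in parent_hashes
        ]
        if leaked:
            raise ValueError(
                f"{len(leaked)} fine-tuning pairs are not part of the "
                f"pre-training training set (first offending index {leaked[0]})"
            )
        child = SequenceToCompoundTransformer(**{**self.get_params(), **overrides})
        child.fit(X, y, _parent=self)
        return child

    # ---- inference -------------------------------------------------------

    def predict(self, X) -> list[str]:
        """Greedy argmax decoding of one SMILES string per sequence."""
        check_is_fitted(self)
        out = []
        for seq in X:
            src = encode_protein(seq, self.src_vocab_, self.permissive_residues)
            toks = self.core_.generate(
                src,
                self.tgt_vocab_.start_id,
                self.tgt_vocab_.end_id,
                self.tgt_vocab_.max_length,
                rng=None,
            )
            out.append("".join(self.tgt_vocab_.tokens[i] for i in toks[0]))
        return out

    def sample_strings(
        self, sequence: str, n: int, temperature: float = 1.0, seed: int = 0
    ) -> list[str]:
        """Multinomial sampling of ``n`` output strings for one sequence.

        Logits are divided by ``temperature`` before the softmax; decoding
        stops at [end] or the vocabulary's maximum length.
        """
        check_is_fitted(self)
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(seed)
        src = encode_protein(sequence, self.src_vocab_, self.permissive_residues)
        token_lists = self.core_.generate(
            src,
            self.tgt_vocab_.start_id,
            self.tgt_vocab_.end_id,
            self.tgt_vocab_.max_length,
            temperature=temperature,
            rng=rng,
            n_samples=n,
        )
        return ["".join(self.tgt_vocab_.tokens[i] for i in toks) for toks in token_lists]

    def sample_strings_many(
        self,
        sequences: list[str],
        n: int,
        temperature: float = 1.0,
        seed: int = 0,
        max_chunk: int = 3000,
    ) -> list[list[str]]:
        """Sample ``n`` strings for each of several sequences in large batches.

        Decoding is batched across sequences (chunked at ``max_chunk``
        samples) so that many short sampling runs — e.g. perturbation
        variants — share one autoregressive loop. Results are grouped per
        input sequence.
        """
        check_is_fitted(self)
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(seed)
        out: list[list[str]] = []
        per_chunk = max(1, max_chunk // n)
        for start in range(0, len(sequences), per_chunk):
            chunk = sequences[start : start + per_chunk]
            src = np.stack(
                [
                    encode_protein(s, self.src_vocab_, self.permissive_residues)
                    for s in chunk
                ]
            )
            grouped = self.core_.generate_many(
                src,
                [n] * len(chunk),
                self.tgt_vocab_.start_id,
                self.tgt_vocab_.end_id,
                self.tgt_vocab_.max_length,
                temperature=temperature,
                rng=rng,
            )
            for token_lists in grouped:
                out.append(
                    [
                        "".join(self.tgt_vocab_.tokens[i] for i in toks)
                        for toks in token_lists
                    ]
                )
        return out

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameters (npz) + JSON sidecar with config/provenance."""
        check_is_fitted(self)
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.core_.params)
        sidecar = {
            "estimator_params": self.get_params(),
            "src_vocab": {
                "tokens": list(self.src_vocab_.tokens),
                "max_length": self.src_vocab_.max_length,
            },
            "tgt_vocab": {
                "tokens": list(self.tgt_vocab_.tokens),
                "max_length": self.tgt_vocab_.max_length,
            },
            "provenance": self.provenance_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceToCompoundTransformer":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        est = cls(**sidecar["estimator_params"])
        est.src_vocab_ = TokenVocabulary(
            tuple(sidecar["src_vocab"]["tokens"]), sidecar["src_vocab"]["max_length"]
        )
        est.tgt_vocab_ = TokenVocabulary(
            tuple(sidecar["tgt_vocab"]["tokens"]), sidecar["tgt_vocab"]["max_length"]
        )
        config = CoreConfig(
            d_model=est.d_model,
            n_heads=est.n_heads,
            n_encoder_layers=est.n_encoder_layers,
            n_decoder_layers=est.n_decoder_layers,
            d_ff=est.d_ff,
            dropout=est.dropout,
            src_vocab_size=est.src_vocab_.size,
            tgt_vocab_size=est.tgt_vocab_.size,
            max_src_len=est.src_vocab_.max_length,
            max_tgt_len=est.tgt_vocab_.max_length,
            dtype=est.dtype,
        )
        est.core_ = TransformerCore(config, np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as data:
            est.core_.params = {k: data[k] for k in data.files}
        est.provenance_ = sidecar["provenance"]
        est.loss_history_ = sidecar["provenance"].get("loss_trajectory", [])
        est.val_loss_history_ = []
        return est


def fit_on_dataset(
    dataset, **estimator_kwargs
) -> SequenceToCompoundTransformer:
    """Convenience: fit an estimator on a PairDataset's (sequence, SMILES) pairs."""
    X = [dataset.sequences[s].residues for s in dataset.pairs["sequence_id"]]
    y = list(dataset.pairs["smiles"])
    return SequenceToCompoundTransformer(**estimator_kwargs).fit(X, y)
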