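"""BiLSTM-CRF sequence tagger.

Architecture: a frozen word-embedding table feeding a stack of bidirectional
LSTM layers (two layers of 300 units per direction by default), a linear
projection to per-token B/I/O emission scores, and a linear-chain CRF output
layer.  Training minimizes the negative sequence log-likelihood with Adam
(batch 128, learning rate 1e-4 by default), stopping early when entity-level
exact-F1 on a validation set stops improving for a configured number of
consecutive epochs; the weights of the best validation epoch are returned.

Everything is plain NumPy with hand-written gradients: the CRF contributes
exact expected-minus-observed sufficient statistics (forward-backward) and
the encoder is differentiated by backpropagation through time.

The per-sentence confidence used by self-training is the exponential of the
length-normalized log-likelihood of the decoded path — the per-word
geometric-mean probability — so confidence thresholds such as 0.9975 are
stated in probability space.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from . import crf
from .corpus import Corpus, Sentence
from .evaluation import evaluate_corpus
from .lstm import DTYPE, BiLSTMLayer

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


class Vocabulary:
    """Token-to-index map with reserved padding (0) and unknown (1) slots."""

    def __init__(self, tokens: Iterable[str]):
        self.index = {PAD_TOKEN: 0, UNK_TOKEN: 1}
        for tok in tokens:
            if tok not in self.index:
                self.index[tok] = len(self.index)

    @classmethod
    def build(cls, *corpora: Corpus) -> "Vocabulary":
        """Vocabulary over the union of the given corpora, in deterministic
        (sorted) order."""
        toks: set[str] = set()
        for corpus in corpora:
            for sent in corpus:
                toks.update(sent.tokens)
        return cls(sorted(toks))

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, tok: str) -> bool:
        return tok in self.index

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        unk = self.index[UNK_TOKEN]
        return np.array([self.index.get(t, unk) for t in tokens], dtype=np.int64)

    def to_list(self) -> list[str]:
        return [t for t, _ in sorted(self.index.items(), key=lambda kv: kv[1])]

    @classmethod
    def from_list(cls, tokens: list[str]) -> "Vocabulary":
        vocab = cls.__new__(cls)
        vocab.index = {t: i for i, t in enumerate(tokens)}
        return vocab


@dataclass(frozen=True)
class TaggerConfig:
    """Hyperparameters; defaults are the full-scale settings (200-d frozen
    embeddings, two 300-unit bidirectional layers, Adam batch 128 lr 1e-4)."""

    embed_dim: int = 200
    hidden_units: int = 300
    recurrent_layers: int = 2
    labels: tuple[str, ...] = ("B", "I", "O")
    batch_size: int = 128
    learning_rate: float = 1e-4
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    freeze_embeddings: bool = True
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "embed_dim",
            "hidden_units",
            "recurrent_layers",
            "batch_size",
            "max_epochs",
            "patience",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.grad_clip <= 0:
            raise ValueError("learning_rate and grad_clip must be positive")
        if tuple(self.labels) != ("B", "I", "O"):
            raise ValueError("labels are fixed to the BIO tag set")

    @classmethod
    def desk_scale(cls, **overrides) -> "TaggerConfig":
        """Reduced preset for CPU-scale synthetic experiments: 50-d
        embeddings, 64 hidden units, and a learning rate scaled up to match
        the far smaller number of optimizer steps per training run."""
        base = dict(
            embed_dim=50,
            hidden_units=64,
            batch_size=32,
            learning_rate=3e-2,
            max_epochs=60,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_exact_f1: float


@dataclass(frozen=True)
class Prediction:
    labels: tuple[str, ...]
    confidence: float
    per_token_scores: tuple[float, ...] | None = None


def load_word_vectors(
    path: str | Path,
    vocabulary: Vocabulary,
    embed_dim: int,
    seed: int = 0,
) -> np.ndarray:
    """Load word2vec text format ("word v1 ... vd" lines, optional
    "count dim" header) into a (V, D) table aligned with ``vocabulary``.

    Out-of-vocabulary rows (including padding and unknown) are drawn from a
    seeded uniform(-0.25, 0.25); in-file rows are copied verbatim.
    """
    rng = np.random.default_rng(seed)
    table = rng.uniform(-0.25, 0.25, size=(len(vocabulary), embed_dim))
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.rstrip("\n").split(" ")
        lines: Iterable[str]
        if len(parts) == 2 and all(p.isdigit() for p in parts):
            if int(parts[1]) != embed_dim:
                raise ValueError(
                    f"word-vector file has dimension {parts[1]}, expected {embed_dim}"
                )
            lines = fh
        else:
            lines = [first] + list(fh)
        for line in lines:
            fields = line.rstrip("\n").split(" ")
            word, values = fields[0], fields[1:]
            if word not in vocabulary:
                continue
            if len(values) != embed_dim:
                raise ValueError(
                    f"vector for {word!r} has dimension {len(values)}, "
                    f"expected {embed_dim}"
                )
            table[vocabulary.index[word]] = [float(v) for v in values]
    table[0] = 0.0  # padding row
    return table


def random_embeddings(
    vocabulary: Vocabulary, embed_dim: int, seed: int = 0
) -> np.ndarray:
    """Seeded uniform(-0.25, 0.25) table used when no external vectors are
    supplied; the padding row is zero."""
    rng = np.random.default_rng(seed)
    table = rng.uniform(-0.25, 0.25, size=(len(vocabulary), embed_dim)).astype(DTYPE)
    table[0] = 0.0
    return table


class _Adam:
    def __init__(self, keys: Iterable[str], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CrfTagger:
    """Trained (or trainable) BiLSTM-CRF over a fixed vocabulary."""

    def __init__(
        self,
        config: TaggerConfig,
        vocabulary: Vocabulary,
        embeddings: np.ndarray | None = None,
    ):
        self.config = config
        self.vocab = vocabulary
        rng = np.random.default_rng(config.seed)
        if embeddings is None:
            embeddings = random_embeddings(vocabulary, config.embed_dim, config.seed)
        if embeddings.shape != (len(vocabulary), config.embed_dim):
            raise ValueError(
                f"embedding table {embeddings.shape} does not match vocabulary "
                f"{len(vocabulary)} x embed_dim {config.embed_dim}"
            )
        self.params: dict[str, np.ndarray] = {
            "embeddings": np.asarray(embeddings, dtype=DTYPE).copy()
        }
        self.layers: list[BiLSTMLayer] = []
        d_in = config.embed_dim
        for l in range(config.recurrent_layers):
            layer = BiLSTMLayer(rng, d_in, config.hidden_units)
            self.layers.append(layer)
            self.params.update(layer.parameters(f"lstm{l}"))
            d_in = 2 * config.hidden_units
        L = len(config.labels)
        self.params["proj.W"] = rng.uniform(
            -np.sqrt(6.0 / (d_in + L)), np.sqrt(6.0 / (d_in + L)), size=(d_in, L)
        ).astype(DTYPE)
        self.params["proj.b"] = np.zeros(L, dtype=DTYPE)
        self.params["transitions"] = np.zeros((L + 2, L + 2), dtype=DTYPE)

    # -- weight plumbing ----------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        if set(weights) != set(self.params):
            raise ValueError("weight archive does not match this architecture")
        self.params = {k: np.asarray(v, dtype=DTYPE).copy() for k, v in weights.items()}
        for l, layer in enumerate(self.layers):
            layer.load(f"lstm{l}", self.params)

    def _sync_layers(self) -> None:
        for l, layer in enumerate(self.layers):
            layer.load(f"lstm{l}", self.params)

    # -- forward / backward -------------------------------------------------

    def _make_batch(
        self, sentences: Sequence[Sentence]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lengths = np.array([len(s) for s in sentences], dtype=np.int64)
        T = int(lengths.max())
        ids = np.zeros((len(sentences), T), dtype=np.int64)
        for b, sent in enumerate(sentences):
            ids[b, : len(sent)] = self.vocab.encode(sent.tokens)
        mask = np.arange(T)[None, :] < lengths[:, None]
        return ids, mask, lengths

    def _encode(
        self, ids: np.ndarray, mask: np.ndarray, lengths: np.ndarray
    ) -> tuple[np.ndarray, list]:
        x = self.params["embeddings"][ids] * mask[:, :, None].astype(DTYPE)
        caches = [("input", ids, x.shape)]
        h = x
        for layer in self.layers:
            h, cache = layer.forward(h, mask, lengths)
            caches.append(("layer", layer, cache))
        emissions = h @ self.params["proj.W"] + self.params["proj.b"]
        caches.append(("proj", h))
        return emissions, caches

    def _backward(
        self, d_emissions: np.ndarray, caches: list
    ) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        kind, h_top = caches[-1]
        assert kind == "proj"
        B, T, _ = d_emissions.shape
        grads["proj.W"] = h_top.reshape(B * T, -1).T @ d_emissions.reshape(B * T, -1)
        grads["proj.b"] = d_emissions.sum(axis=(0, 1))
        d_h = d_emissions @ self.params["proj.W"].T
        for l in range(len(self.layers) - 1, -1, -1):
            kind, layer, cache = caches[1 + l]
            d_h, layer_grads = layer.backward(cache, d_h)
            for k, v in layer_grads.items():
                grads[f"lstm{l}.{k}"] = v
        if not self.config.freeze_embeddings:
            _, ids, shape = caches[0]
            d_emb = np.zeros_like(self.params["embeddings"])
            np.add.at(d_emb, ids.reshape(-1), d_h.reshape(-1, shape[-1]))
            d_emb[0] = 0.0
            grads["embeddings"] = d_emb
        return grads

    def _loss_and_grads(
        self, sentences: Sequence[Sentence]
    ) -> tuple[float, dict[str, np.ndarray]]:
        ids, mask, lengths = self._make_batch(sentences)
        labels = np.zeros_like(ids)
        for b, sent in enumerate(sentences):
            labels[b, : len(sent)] = [crf.LABEL_TO_INDEX[l] for l in sent.labels]
        emissions, caches = self._encode(ids, mask, lengths)
        nll, d_em, d_trans = crf.batch_nll_grad(
            emissions, self.params["transitions"], labels, mask
        )
        scale = 1.0 / len(sentences)
        grads = self._backward(d_em * scale, caches)
        grads["transitions"] = d_trans * scale
        return float(nll.mean()), grads

    # -- training -----------------------------------------------------------

    def fit(
        self,
        train: Corpus,
        val: Corpus,
        evaluator: Callable[["CrfTagger", Corpus], float] | None = None,
    ) -> list[EpochRecord]:
        """Train with Adam and exact-F1 early stopping.

        Stops when the validation score has not improved for
        ``config.patience`` consecutive epochs (or at ``max_epochs``) and
        restores the weights of the best epoch.  ``evaluator`` defaults to
        entity-level exact-F1 on ``val``.
        """
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and val must be non-empty")
        for corpus in (train, val):
            for sent in corpus:
                if sent.labels is None:
                    raise ValueError(f"unlabeled sentence {sent.id!r} in training data")
        if evaluator is None:
            evaluator = exact_f1_evaluator
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        trainable = [k for k in self.params if k != "embeddings"]
        if not cfg.freeze_embeddings:
            trainable.append("embeddings")
        optimizer = _Adam(trainable, cfg.learning_rate)

        history: list[EpochRecord] = []
        best_f1 = -np.inf
        best_weights = self.get_weights()
        since_improve = 0
        order_pool = np.arange(len(train))
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(order_pool)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = [train[i] for i in order[start : start + cfg.batch_size]]
                loss, grads = self._loss_and_grads(batch)
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if norm > cfg.grad_clip:
                    grads = {k: g * (cfg.grad_clip / norm) for k, g in grads.items()}
                optimizer.step(self.params, grads)
                losses.append(loss)
            self._sync_layers()
            val_f1 = evaluator(self, val)
            history.append(EpochRecord(epoch, float(np.mean(losses)), val_f1))
            if val_f1 > best_f1:
                best_f1 = val_f1
                best_weights = self.get_weights()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= cfg.patience:
                    break
        self.set_weights(best_weights)
        return history

    # -- inference ----------------------------------------------------------

    def predict(self, sentences: Sequence[Sentence]) -> list[Prediction]:
        """Viterbi labels and per-sentence confidence for each sentence;
        deterministic for fixed weights."""
        if len(sentences) == 0:
            return []
        out: list[Prediction] = []
        bs = max(256, self.config.batch_size)
        for start in range(0, len(sentences), bs):
            chunk = sentences[start : start + bs]
            ids, mask, lengths = self._make_batch(chunk)
            emissions, _ = self._encode(ids, mask, lengths)
            # float64 for decoding/confidence so near-certain paths do not
            # round up to a confidence of exactly 1.0
            emissions = emissions.astype(np.float64)
            trans = self.params["transitions"].astype(np.float64)
            paths, scores = crf.batch_viterbi(emissions, trans, mask)
            logZ = crf.batch_log_partition(emissions, trans, mask)
            for b, sent in enumerate(chunk):
                n = int(lengths[b])
                labels = tuple(crf.INDEX_TO_LABEL[i] for i in paths[b, :n])
                conf = float(np.exp((scores[b] - logZ[b]) / n))
                out.append(Prediction(labels=labels, confidence=min(conf, 1.0)))
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: named arrays plus config/vocabulary."""
        meta = {
            "config": asdict(self.config),
            "vocab": self.vocab.to_list(),
        }
        arrays = {k.replace(".", "__"): v for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CrfTagger":
        with np.load(path) as archive:
            meta = json.loads(archive["__meta__"].tobytes().decode())
            params = {
                k.replace("__", "."): archive[k]
                for k in archive.files
                if k != "__meta__"
            }
        meta["config"]["labels"] = tuple(meta["config"]["labels"])
        config = TaggerConfig(**meta["config"])
        vocab = Vocabulary.from_list(meta["vocab"])
        tagger = cls(config, vocab)
        tagger.set_weights(params)
        return tagger


def exact_f1_evaluator(tagger: CrfTagger, val: Corpus) -> float:
    preds = tagger.predict(val.sentences)
    return evaluate_corpus(val, [p.labels for p in preds]).exact_f1


def fit(
    config: TaggerConfig,
    train: Corpus,
    val: Corpus,
    vocabulary: Vocabulary | None = None,
    init_weights: dict[str, np.ndarray] | None = None,
    embeddings: np.ndarray | None = None,
    evaluator: Callable[[CrfTagger, Corpus], float] | None = None,
) -> tuple[CrfTagger, list[EpochRecord]]:
    """Construct a tagger (fresh seeded init, or from ``init_weights``) and
    train it; returns the tagger and the per-epoch log."""
    if vocabulary is None:
        vocabulary = Vocabulary.build(train, val)
    tagger = CrfTagger(config, vocabulary, embeddings=embeddings)
    if init_weights is not None:
        tagger.set_weights(init_weights)
    history = tagger.fit(train, val, evaluator=evaluator)
    return tagger, history
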