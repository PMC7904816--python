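"""Hierarchical bi-LSTM relation detection.

Given a sentence with one microbe and one disease mention, the detector
decides whether the sentence asserts an association.  The two entities
split the sentence into three phrases (Seq1 before the first entity,
Seq2 between them, Seq3 after the second); together with the shortest
dependency path (SDP) between the entity tokens these form four token
sequences.  Each token is represented by the concatenation of its word
vector, a POS-tag embedding, a dependency-tag embedding, and a relative
position one-hot pair (default dims 200 + 10 + 10 + 20).

An entity-based attention layer reweights word vectors before the
recurrent layers: for each entity k the weight of token i is

    theta_i^k = softmax_i( w_i . e_k ),     theta_i = (theta_i^1 + theta_i^2) / 2

Four many-to-one bi-LSTMs (hidden size h, default 100) encode the four
sequences into 2h-vectors; interleaved with the two entity embeddings in
sentence order [Seq1, E1, Seq2, E2, Seq3, SDP] they form a 6 x 2h matrix
that a top bi-LSTM reduces to a single 2h-vector, followed by a linear
softmax head over {no relation, relation}.  With the default geometry
the bottom layer output is the paper-architecture 4 x 200 matrix and the
top input 6 x 200.

Training uses Adam on cross-entropy with inverted dropout on the input
and pre-softmax activations; everything is seeded and deterministic.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ner import MICROBE, DISEASE, EntityMention
from .trees import DependencyTree, ParsedSentence


# ---------------------------------------------------------------------------
# candidate pairs


@dataclass
class CandidatePair:
    """One microbe mention x one disease mention within a sentence.

    ``e1``/``e2`` are the first/second entity in token order; ``microbe``
    and ``disease`` give the class-specific view.  ``seq1``..``seq3`` are
    half-open token spans partitioning the sentence around the entities;
    ``sdp`` lists the tokens strictly between the entities on the unique
    dependency path, in sentence order.
    """

    sentence: ParsedSentence
    microbe: EntityMention
    disease: EntityMention
    label: int | None = None
    seq1: tuple[int, int] = (0, 0)
    seq2: tuple[int, int] = (0, 0)
    seq3: tuple[int, int] = (0, 0)
    sdp: list[int] = field(default_factory=list)

    @property
    def e1(self) -> EntityMention:
        return self.microbe if self.microbe.index < self.disease.index else self.disease

    @property
    def e2(self) -> EntityMention:
        return self.disease if self.microbe.index < self.disease.index else self.microbe

    @property
    def pair_id(self) -> tuple[str, str, str]:
        return (self.sentence.sentence.sentence_id,
                self.microbe.tagged_token, self.disease.tagged_token)


def segment(pair: CandidatePair) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Token spans before / between / after the two entities."""
    n = len(pair.sentence.sentence.tokens)
    i1, i2 = pair.e1.index, pair.e2.index
    return (0, i1), (i1 + 1, i2), (i2 + 1, n)


def shortest_dep_path(pair: CandidatePair, dtree: DependencyTree) -> list[int]:
    """Interior tokens of the dependency path between the entities."""
    full = dtree.path(pair.e1.index, pair.e2.index)
    return sorted(full[1:-1])


def enumerate_pairs(sentence: ParsedSentence) -> list[CandidatePair]:
    """Cartesian product of microbe x disease mentions, segments and SDP set."""
    microbes = sentence.sentence.mentions_of(MICROBE)
    diseases = sentence.sentence.mentions_of(DISEASE)
    pairs = []
    for m, d in product(microbes, diseases):
        pair = CandidatePair(sentence=sentence, microbe=m, disease=d)
        pair.seq1, pair.seq2, pair.seq3 = segment(pair)
        pair.sdp = shortest_dep_path(pair, sentence.dtree)
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# configuration and embeddings


@dataclass
class DetectorConfig:
    word_dim: int = 200
    pos_dim: int = 10
    dep_dim: int = 10
    position_dim: int = 20  # two concatenated 10-bin one-hots
    seg_time_steps: int = 60
    sdp_time_steps: int = 12
    hidden: int = 100
    learning_rate: float = 0.001
    epochs: int = 30
    batch_size: int = 32
    input_dropout: float = 0.7  # keep-probability by default
    output_dropout: float = 0.5
    dropout_semantics: str = "keep"  # "keep" or "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("word_dim", "pos_dim", "dep_dim", "seg_time_steps",
                     "sdp_time_steps", "hidden", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for name in ("input_dropout", "output_dropout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.position_dim % 2:
            raise ValueError("position_dim must be even (two one-hot halves)")
        if self.dropout_semantics not in ("keep", "drop"):
            raise ValueError("dropout_semantics must be 'keep' or 'drop'")

    @property
    def feature_dim(self) -> int:
        return self.word_dim + self.pos_dim + self.dep_dim + self.position_dim

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "DetectorConfig":
        """Reduced geometry of the same architecture for single-CPU runs.

        Word dim 50, hidden 32, time steps sized to the synthetic
        templates; training converges in a handful of epochs at a
        slightly higher Adam step.
        """
        return cls(word_dim=50, hidden=32, seg_time_steps=8, sdp_time_steps=6,
                   epochs=6, batch_size=64, learning_rate=0.003, seed=seed)

    def keep_probs(self) -> tuple[float, float]:
        if self.dropout_semantics == "keep":
            return self.input_dropout, self.output_dropout
        return 1.0 - self.input_dropout, 1.0 - self.output_dropout


class WordVectors:
    """Word vector store: file-loaded vectors plus deterministic OOV draws.

    Out-of-vocabulary tokens get a fixed pseudo-random unit-scaled vector
    derived from a hash of the token and the seed, so vectors are stable
    across runs and processes without any pretraining.
    """

    def __init__(self, dim: int, vectors: dict[str, np.ndarray] | None = None,
                 seed: int = 0):
        self.dim = dim
        self.vectors = dict(vectors or {})
        self.seed = seed

    @classmethod
    def load_word2vec_text(cls, path: str | Path, seed: int = 0) -> "WordVectors":
        """Read word2vec text format (optional count/dim header line)."""
        vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().split()
            if len(first) == 2 and all(p.isdigit() for p in first):
                dim = int(first[1])
            elif first:
                vectors[first[0]] = np.array([float(x) for x in first[1:]])
                dim = len(first) - 1
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                vec = np.array([float(x) for x in parts[1:]])
                if dim is not None and len(vec) != dim:
                    raise ValueError(f"{path}: inconsistent vector size for {parts[0]!r}")
                vectors[parts[0]] = vec
        if dim is None:
            raise ValueError(f"{path}: empty embedding file")
        return cls(dim=dim, vectors=vectors, seed=seed)

    def get(self, token: str) -> np.ndarray:
        token = token.lower()
        if token not in self.vectors:
            digest = hashlib.sha256(f"{self.seed}:{token}".encode()).digest()
            rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest[:8], "little")))
            self.vectors[token] = rng.standard_normal(self.dim) / np.sqrt(self.dim)
        return self.vectors[token]

    def entity_vector(self, canonical: str) -> np.ndarray:
        """Mean of the constituent-word vectors of the canonical name."""
        parts = [p for p in canonical.split("_") if p]
        return np.mean([self.get(p) for p in parts], axis=0)


def attention_weights(word_vecs: np.ndarray, e1_vec: np.ndarray,
                      e2_vec: np.ndarray) -> np.ndarray:
    """Entity-based attention: mean of per-entity softmaxed dot products."""
    if word_vecs.ndim != 2 or word_vecs.shape[0] == 0:
        raise ValueError("attention needs a non-empty [m, dim] word matrix")
    weights = []
    for e in (e1_vec, e2_vec):
        scores = word_vecs @ e
        scores = scores - scores.max()
        ez = np.exp(scores)
        weights.append(ez / ez.sum())
    return (weights[0] + weights[1]) / 2.0


# ---------------------------------------------------------------------------
# featurisation


@dataclass
class PairFeatures:
    """Dense, padded feature arrays for one candidate pair.

    Segment arrays have shape [T, feature_dim] with all-zero padding
    rows; ``*_len`` give true lengths; ``*_ids`` are vocabulary indices
    into the trainable POS/dep embedding tables (0 = padding).  The word
    block of each row is already attention-weighted.
    """

    segs: np.ndarray  # [4, T_max, feature_dim-pos_dim-dep_dim] word+position part
    seg_pos_ids: np.ndarray  # [4, T_max] int
    seg_dep_ids: np.ndarray  # [4, T_max] int
    seg_lens: np.ndarray  # [4] int
    e1_vec: np.ndarray
    e2_vec: np.ndarray
    label: int = -1


class Vocabulary:
    """Index for POS and dependency tags (0 reserved for padding)."""

    def __init__(self) -> None:
        self.index: dict[str, int] = {"<pad>": 0}

    def add(self, tag: str) -> int:
        if tag not in self.index:
            self.index[tag] = len(self.index)
        return self.index[tag]

    def get(self, tag: str) -> int:
        return self.index.get(tag, 0)

    def __len__(self) -> int:
        return len(self.index)


def _truncate(indices: list[int], limit: int, keep_end: str) -> list[int]:
    """Truncate at the end farthest from the nearest entity."""
    if len(indices) <= limit:
        return indices
    if keep_end == "right":
        return indices[-limit:]
    if keep_end == "left":
        return indices[:limit]
    # middle segment: keep both entity-adjacent ends, drop the centre
    half = limit // 2
    return indices[:half] + indices[len(indices) - (limit - half):]


def featurize(pair: CandidatePair, words: WordVectors, config: DetectorConfig,
              pos_vocab: Vocabulary, dep_vocab: Vocabulary,
              grow_vocab: bool = False) -> PairFeatures:
    sent = pair.sentence
    tokens = sent.sentence.tokens
    dtree = sent.dtree
    pos_tags = dtree.pos
    dep_tags = dtree.labels
    i1, i2 = pair.e1.index, pair.e2.index

    word_mat = np.stack([words.get(t) for t in tokens])
    e1_vec = words.entity_vector(pair.e1.canonical)
    e2_vec = words.entity_vector(pair.e2.canonical)
    theta = attention_weights(word_mat, e1_vec, e2_vec)
    # attention as multiplicative reweighting, rescaled by sentence length
    # so weighted vectors keep unit-order magnitude
    weighted = word_mat * (theta * len(tokens))[:, None]

    half = config.position_dim // 2

    def position_onehot(idx: int) -> np.ndarray:
        # relative distance to each entity, clipped to [-(half//2 - 1), half//2],
        # i.e. [-4, +5] for the default 10-bin halves, one bin per value
        vec = np.zeros(config.position_dim)
        lo = -(half // 2 - 1)
        hi = lo + half - 1
        for k, ent in enumerate((i1, i2)):
            rel = min(max(idx - ent, lo), hi)
            vec[k * half + (rel - lo)] = 1.0
        return vec

    spans = [
        _truncate(list(range(*pair.seq1)), config.seg_time_steps, "right"),
        _truncate(list(range(*pair.seq2)), config.seg_time_steps, "middle"),
        _truncate(list(range(*pair.seq3)), config.seg_time_steps, "left"),
        _truncate(list(pair.sdp), config.sdp_time_steps, "middle"),
    ]
    t_max = max(config.seg_time_steps, config.sdp_time_steps)
    dense_dim = config.word_dim + config.position_dim
    segs = np.zeros((4, t_max, dense_dim))
    pos_ids = np.zeros((4, t_max), dtype=np.int64)
    dep_ids = np.zeros((4, t_max), dtype=np.int64)
    lens = np.zeros(4, dtype=np.int64)
    for s, idxs in enumerate(spans):
        lens[s] = len(idxs)
        for t, idx in enumerate(idxs):
            segs[s, t, : config.word_dim] = weighted[idx]
            segs[s, t, config.word_dim:] = position_onehot(idx)
            if grow_vocab:
                pos_ids[s, t] = pos_vocab.add(pos_tags[idx])
                dep_ids[s, t] = dep_vocab.add(dep_tags[idx])
            else:
                pos_ids[s, t] = pos_vocab.get(pos_tags[idx])
                dep_ids[s, t] = dep_vocab.get(dep_tags[idx])
    return PairFeatures(segs=segs, seg_pos_ids=pos_ids, seg_dep_ids=dep_ids,
                        seg_lens=lens, e1_vec=e1_vec, e2_vec=e2_vec,
                        label=pair.label if pair.label is not None else -1)


# ---------------------------------------------------------------------------
# model


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class LSTMCellParams:
    def __init__(self, rng: np.random.Generator, input_dim: int, hidden: int,
                 prefix: str, params: dict[str, Tensor]):
        self.hidden = hidden
        self.Wx = Tensor(_glorot(rng, (input_dim, 4 * hidden)), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, (hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b[None, :], requires_grad=True)
        params[f"{prefix}.Wx"] = self.Wx
        params[f"{prefix}.Wh"] = self.Wh
        params[f"{prefix}.b"] = self.b

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = x @ self.Wx + h @ self.Wh + self.b
        hd = self.hidden
        i = z.slice_cols(0, hd).sigmoid()
        f = z.slice_cols(hd, 2 * hd).sigmoid()
        g = z.slice_cols(2 * hd, 3 * hd).tanh()
        o = z.slice_cols(3 * hd, 4 * hd).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


def _run_lstm(cell: LSTMCellParams, xs: list[Tensor], mask: np.ndarray) -> Tensor:
    """Many-to-one masked LSTM; returns the state at each true length.

    ``mask`` is [B, T]; update rows are frozen once past the true length,
    so the final state equals the state at the last true token and extra
    padding never changes the output.
    """
    batch = xs[0].data.shape[0]
    h = Tensor(np.zeros((batch, cell.hidden)))
    c = Tensor(np.zeros((batch, cell.hidden)))
    for t, x in enumerate(xs):
        m = mask[:, t][:, None]
        h_new, c_new = cell.step(x, h, c)
        h = h_new * m + h * (1.0 - m)
        c = c_new * m + c * (1.0 - m)
    return h


class DetectorModel:
    """Weights and forward pass of the hierarchical bi-LSTM."""

    SEG_NAMES = ("seq1", "seq2", "seq3", "sdp")

    def __init__(self, config: DetectorConfig, pos_vocab_size: int,
                 dep_vocab_size: int):
        self.config = config
        self.pos_vocab_size = pos_vocab_size
        self.dep_vocab_size = dep_vocab_size
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self.params: dict[str, Tensor] = {}
        c = config
        self.pos_emb = Tensor(rng.standard_normal((pos_vocab_size, c.pos_dim)) * 0.1,
                              requires_grad=True)
        self.dep_emb = Tensor(rng.standard_normal((dep_vocab_size, c.dep_dim)) * 0.1,
                              requires_grad=True)
        self.params["pos_emb"] = self.pos_emb
        self.params["dep_emb"] = self.dep_emb
        self.cells: dict[str, LSTMCellParams] = {}
        for name in self.SEG_NAMES:
            for direction in ("fwd", "bwd"):
                self.cells[f"{name}.{direction}"] = LSTMCellParams(
                    rng, c.feature_dim, c.hidden, f"bottom.{name}.{direction}",
                    self.params)
        for direction in ("fwd", "bwd"):
            self.cells[f"top.{direction}"] = LSTMCellParams(
                rng, 2 * c.hidden, c.hidden, f"top.{direction}", self.params)
        if c.word_dim != 2 * c.hidden:
            self.entity_proj = Tensor(_glorot(rng, (c.word_dim, 2 * c.hidden)),
                                      requires_grad=True)
            self.params["entity_proj"] = self.entity_proj
        else:
            self.entity_proj = None
        self.W_out = Tensor(_glorot(rng, (2 * c.hidden, 2)), requires_grad=True)
        self.b_out = Tensor(np.zeros((1, 2)), requires_grad=True)
        self.params["W_out"] = self.W_out
        self.params["b_out"] = self.b_out

    # ------------------------------------------------------------- forward

    def _bottom(self, batch: list[PairFeatures],
                dropout_rng: np.random.Generator | None) -> tuple[list[Tensor], dict]:
        c = self.config
        bsz = len(batch)
        keep_in, _ = c.keep_probs()
        seg_outputs: list[Tensor] = []
        trace: dict = {}
        for s, name in enumerate(self.SEG_NAMES):
            t_steps = c.sdp_time_steps if name == "sdp" else c.seg_time_steps
            dense = np.stack([f.segs[s, :t_steps] for f in batch])  # [B,T,dd]
            pos_ids = np.stack([f.seg_pos_ids[s, :t_steps] for f in batch])
            dep_ids = np.stack([f.seg_dep_ids[s, :t_steps] for f in batch])
            lens = np.array([f.seg_lens[s] for f in batch])
            mask = (np.arange(t_steps)[None, :] < lens[:, None]).astype(float)
            # per-sample reversal indices for the backward direction
            # (padding rows map to themselves and stay masked out)
            tr = np.arange(t_steps)[None, :]
            rev = np.where(tr < lens[:, None], lens[:, None] - 1 - tr, tr)
            rows = np.arange(bsz)[:, None]

            def steps(dense_arr, pos_arr, dep_arr) -> list[Tensor]:
                xs: list[Tensor] = []
                for t in range(t_steps):
                    word_part = Tensor(dense_arr[:, t, : c.word_dim])
                    posn_part = Tensor(dense_arr[:, t, c.word_dim:])
                    pos_part = ad.gather_rows(self.pos_emb, pos_arr[:, t])
                    dep_part = ad.gather_rows(self.dep_emb, dep_arr[:, t])
                    x = ad.concat([word_part, pos_part, dep_part, posn_part], axis=1)
                    if dropout_rng is not None and keep_in < 1.0:
                        drop = (dropout_rng.random((bsz, c.feature_dim)) < keep_in)
                        x = x * (drop.astype(float) / keep_in)
                    xs.append(x)
                return xs

            h_fwd = _run_lstm(self.cells[f"{name}.fwd"],
                              steps(dense, pos_ids, dep_ids), mask)
            h_bwd = _run_lstm(self.cells[f"{name}.bwd"],
                              steps(dense[rows, rev], pos_ids[rows, rev],
                                    dep_ids[rows, rev]), mask)
            out = ad.concat([h_fwd, h_bwd], axis=1)  # [B, 2h]
            # an empty segment contributes a zero vector
            nonzero = (lens > 0).astype(float)[:, None]
            out = out * nonzero
            seg_outputs.append(out)
            trace[name] = out
        return seg_outputs, trace

    def forward(self, batch: list[PairFeatures],
                dropout_rng: np.random.Generator | None = None,
                return_trace: bool = False):
        """Probability of association per pair (batch).

        In inference mode (no dropout generator) the pass is
        deterministic.  With ``return_trace`` the bottom 4 x 2h matrix
        and top 6 x 2h input are also returned for inspection.
        """
        c = self.config
        seg_outputs, trace = self._bottom(batch, dropout_rng)
        e1 = Tensor(np.stack([f.e1_vec for f in batch]))
        e2 = Tensor(np.stack([f.e2_vec for f in batch]))
        if self.entity_proj is not None:
            e1 = e1 @ self.entity_proj
            e2 = e2 @ self.entity_proj
        # sentence order: Seq1, E1, Seq2, E2, Seq3, then the SDP encoding
        top_steps = [seg_outputs[0], e1, seg_outputs[1], e2, seg_outputs[2],
                     seg_outputs[3]]
        mask = np.ones((len(batch), 6))
        h_fwd = _run_lstm(self.cells["top.fwd"], top_steps, mask)
        h_bwd = _run_lstm(self.cells["top.bwd"], top_steps[::-1], mask)
        top_out = ad.concat([h_fwd, h_bwd], axis=1)  # [B, 2h]
        _, keep_out = c.keep_probs()
        if dropout_rng is not None and keep_out < 1.0:
            drop = (dropout_rng.random(top_out.data.shape) < keep_out)
            top_out = top_out * (drop.astype(float) / keep_out)
        logits = top_out @ self.W_out + self.b_out
        if return_trace:
            trace["bottom_matrix"] = np.stack(
                [t.data for t in seg_outputs], axis=1)  # [B, 4, 2h]
            trace["top_input"] = np.stack(
                [t.data for t in top_steps], axis=1)  # [B, 6, 2h]
            trace["top_output"] = top_out.data
            return logits, trace
        return logits

    def predict_proba(self, features: list[PairFeatures],
                      batch_size: int = 64) -> np.ndarray:
        """P(association) per pair, deterministic."""
        probs = []
        for start in range(0, len(features), batch_size):
            chunk = features[start: start + batch_size]
            logits = self.forward(chunk)
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            ez = np.exp(z)
            probs.append((ez / ez.sum(axis=1, keepdims=True))[:, 1])
        return np.concatenate(probs) if probs else np.zeros(0)

    # ---------------------------------------------------------- persistence

    def save(self, path: str | Path, pos_vocab: Vocabulary,
             dep_vocab: Vocabulary) -> None:
        """Single-file checkpoint: config + vocabularies + weights."""
        arrays = {k: p.data for k, p in self.params.items()}
        meta = {
            "config": asdict(self.config),
            "pos_vocab": pos_vocab.index,
            "dep_vocab": dep_vocab.index,
        }
        np.savez(path, __meta__=np.frombuffer(
            zlib.compress(json.dumps(meta).encode()), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path, config: DetectorConfig | None = None
             ) -> tuple["DetectorModel", Vocabulary, Vocabulary]:
        with np.load(path) as data:
            meta = json.loads(zlib.decompress(data["__meta__"].tobytes()))
            saved_config = DetectorConfig(**meta["config"])
            if config is not None and asdict(config) != asdict(saved_config):
                raise ValueError("checkpoint config does not match requested config")
            pos_vocab, dep_vocab = Vocabulary(), Vocabulary()
            pos_vocab.index = {k: int(v) for k, v in meta["pos_vocab"].items()}
            dep_vocab.index = {k: int(v) for k, v in meta["dep_vocab"].items()}
            model = cls(saved_config, len(pos_vocab), len(dep_vocab))
            for k, p in model.params.items():
                p.data = data[k]
        return model, pos_vocab, dep_vocab


# ---------------------------------------------------------------------------
# training and evaluation


def train(features: list[PairFeatures], config: DetectorConfig,
          pos_vocab: Vocabulary, dep_vocab: Vocabulary,
          ) -> tuple[DetectorModel, list[float]]:
    """Train a detector; deterministic under ``config.seed``.

    Returns the model and the per-epoch mean loss trace.  A single-class
    dataset is an error.
    """
    labels = np.array([f.label for f in features])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    model = DetectorModel(config, len(pos_vocab), len(dep_vocab))
    opt = ad.Adam(model.params, lr=config.learning_rate)
    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    losses: list[float] = []
    n = len(features)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            batch = [features[i] for i in idx]
            y = labels[idx]
            opt.zero_grad()
            logits = model.forward(batch, dropout_rng=rng)
            loss, _ = ad.softmax_cross_entropy(logits, y)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return model, losses


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def evaluate(model: DetectorModel, features: list[PairFeatures],
             pair_sentences: list[str] | None = None,
             level: str = "pair") -> tuple[float, float, float]:
    """Precision / recall / F at pair or sentence level.

    Sentence level: a sentence is positive if any of its pairs is
    (gold and predicted alike).  Ties at probability 0.5 predict
    negative.
    """
    probs = model.predict_proba(features)
    preds = (probs > 0.5).astype(int)
    gold = np.array([f.label for f in features])
    if level == "sentence":
        if pair_sentences is None:
            raise ValueError("sentence-level evaluation needs sentence ids")
        agg_gold: dict[str, int] = {}
        agg_pred: dict[str, int] = {}
        for sid, g, p in zip(pair_sentences, gold, preds):
            agg_gold[sid] = max(agg_gold.get(sid, 0), int(g))
            agg_pred[sid] = max(agg_pred.get(sid, 0), int(p))
        gold = np.array([agg_gold[s] for s in sorted(agg_gold)])
        preds = np.array([agg_pred[s] for s in sorted(agg_pred)])
    tp = int(((preds == 1) & (gold == 1)).sum())
    fp = int(((preds == 1) & (gold == 0)).sum())
    fn = int(((preds == 0) & (gold == 1)).sum())
    return prf(tp, fp, fn)
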