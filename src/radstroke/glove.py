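"""Domain word-embedding training (GloVe).

Co-occurrence counts are accumulated over a symmetric window within each
sentence, weighted by inverse distance. Vectors are then fitted by
minimizing the weighted least-squares objective

    J = sum_{ij : X_ij > 0} f(X_ij) (w_i . w~_j + b_i + b~_j - ln X_ij)^2
    f(x) = (x / x_max)^alpha  for x < x_max, else 1

with AdaGrad updates over the nonzero entries, visited in a seeded shuffled
order each epoch. Defaults: 100-dimensional vectors, 50 epochs, window of
10 tokens, initial learning rate 0.05; x_max=100 and alpha=0.75 are the
method's canonical weighting constants. The exported vector for a token is
w_i + w~_i (sum of main and context vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .featurize import Vocabulary
from .io import EmbeddingFile
from .preprocess import TokenDoc


@dataclass
class GloveConfig:
    d: int = 100
    iters: int = 50
    window: int = 10
    lr: float = 0.05
    x_max: float = 100.0
    alpha: float = 0.75
    seed: int = 0
    cross_sentence: bool = False  # let windows span sentence boundaries

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.iters < 0:
            raise ValueError("iters must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class CooccurrenceMatrix:
    """Symmetric sparse co-occurrence weights over a fitted vocabulary."""

    vocab: Vocabulary
    X: sp.csr_matrix

    @property
    def nnz(self) -> int:
        return self.X.nnz


@dataclass
class GloveModel:
    W: np.ndarray
    W_context: np.ndarray
    b: np.ndarray
    b_context: np.ndarray
    loss_history: list[float] = field(default_factory=list)


def build_cooccurrence(
    corpus: list[TokenDoc],
    vocab: Vocabulary,
    window: int = 10,
    cross_sentence: bool = False,
) -> CooccurrenceMatrix:
    """Accumulate 1/distance weights for every in-window ordered token pair.

    Windows are symmetric; by default sentence boundaries block
    co-occurrence. A token never co-occurs with itself (same-vocabulary-index
    pairs are skipped), keeping the diagonal exactly zero.
    """
    V = len(vocab)
    counts: dict[tuple[int, int], float] = {}
    for doc in corpus:
        spans = [doc.tokens()] if cross_sentence else doc.sentences
        for sent in spans:
            ids = [vocab.index[t] for t in sent if t in vocab.index]
            n = len(ids)
            for pos in range(n):
                i = ids[pos]
                for off in range(1, min(window, n - 1 - pos) + 1):
                    j = ids[pos + off]
                    if i == j:
                        continue
                    w = 1.0 / off
                    counts[(i, j)] = counts.get((i, j), 0.0) + w
                    counts[(j, i)] = counts.get((j, i), 0.0) + w
    if counts:
        rows, cols = zip(*counts)
        data = [counts[k] for k in counts]
        X = sp.csr_matrix((data, (rows, cols)), shape=(V, V))
    else:
        X = sp.csr_matrix((V, V))
    return CooccurrenceMatrix(vocab=vocab, X=X)


def train_glove(cooc: CooccurrenceMatrix, cfg: GloveConfig, chunk: int = 1024) -> GloveModel:
    """Fit GloVe vectors by AdaGrad on the weighted least-squares objective.

    Entries are visited in a freshly shuffled order each epoch (seeded);
    updates are applied in vectorized chunks with per-parameter accumulated
    squared gradients. ``iters=0`` returns the seeded initialization.
    """
    coo = cooc.X.tocoo()
    if coo.nnz == 0:
        raise ValueError("no co-occurrence mass: cannot train embeddings")
    V = cooc.X.shape[0]
    d = cfg.d
    rng = np.random.default_rng(cfg.seed)

    W = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d))
    Wc = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d))
    b = rng.uniform(-0.5 / d, 0.5 / d, size=V)
    bc = rng.uniform(-0.5 / d, 0.5 / d, size=V)
    gW = np.ones((V, d))
    gWc = np.ones((V, d))
    gb = np.ones(V)
    gbc = np.ones(V)

    rows = coo.row.astype(np.intp)
    cols = coo.col.astype(np.intp)
    logx = np.log(coo.data)
    fw = np.minimum((coo.data / cfg.x_max) ** cfg.alpha, 1.0)

    history: list[float] = []
    for _ in range(cfg.iters):
        order = rng.permutation(coo.nnz)
        total = 0.0
        for start in range(0, coo.nnz, chunk):
            sel = order[start : start + chunk]
            i, j = rows[sel], cols[sel]
            f = fw[sel]
            diff = np.einsum("ij,ij->i", W[i], Wc[j]) + b[i] + bc[j] - logx[sel]
            total += float(np.sum(f * diff * diff))
            fdiff = np.clip(f * diff, -100.0, 100.0)

            grad_wi = fdiff[:, None] * Wc[j]
            grad_wj = fdiff[:, None] * W[i]
            upd_wi = cfg.lr * grad_wi / np.sqrt(gW[i])
            upd_wj = cfg.lr * grad_wj / np.sqrt(gWc[j])
            upd_bi = cfg.lr * fdiff / np.sqrt(gb[i])
            upd_bj = cfg.lr * fdiff / np.sqrt(gbc[j])

            np.subtract.at(W, i, upd_wi)
            np.subtract.at(Wc, j, upd_wj)
            np.subtract.at(b, i, upd_bi)
            np.subtract.at(bc, j, upd_bj)
            np.add.at(gW, i, grad_wi**2)
            np.add.at(gWc, j, grad_wj**2)
            np.add.at(gb, i, fdiff**2)
            np.add.at(gbc, j, fdiff**2)
        history.append(total)
        if not (
            np.all(np.isfinite(W))
            and np.all(np.isfinite(Wc))
            and np.all(np.isfinite(b))
            and np.all(np.isfinite(bc))
        ):
            raise FloatingPointError("non-finite parameters during GloVe training")

    return GloveModel(W=W, W_context=Wc, b=b, b_context=bc, loss_history=history)


def export_embeddings(model: GloveModel, vocab: Vocabulary) -> EmbeddingFile:
    """Embedding per token: sum of main and context vectors, vocab order."""
    return EmbeddingFile(tokens=vocab.tokens, vectors=model.W + model.W_context)


def nearest_neighbors(emb: EmbeddingFile, token: str, k: int) -> list[tuple[str, float]]:
    """k most cosine-similar tokens to ``token``, query excluded.

    Descending similarity, ties broken lexicographically.
    """
    if token not in emb:
        raise KeyError(f"token {token!r} not in embedding vocabulary")
    if k >= len(emb):
        raise ValueError("k must be smaller than the vocabulary size")
    q = emb.vector(token)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(emb.vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = emb.vectors @ q / np.where(norms * qn > 0, norms * qn, np.inf)
    ranked = sorted(
        ((t, float(s)) for t, s in zip(emb.tokens, sims) if t != token),
        key=lambda ts: (-ts[1], ts[0]),
    )
    return ranked[:k]
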