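"""Hierarchical LSTM document classifier, implemented in numpy.

Architecture: a word-level LSTM reads each sentence's embedded token
sequence and emits its final hidden state as the sentence vector; a
sentence-level LSTM reads the sequence of sentence vectors and emits a
document vector; an affine + logistic head maps the document vector to a
class probability. Embedding rows are frozen (not trained). Training is
mini-batch gradient descent on the binary log-loss with Adam; all
randomness (initialization, batch shuffling) is driven by one seed.

Backpropagation through both recurrent levels is written out explicitly
and verified against numerical gradients in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import EmbeddingFile
from .preprocess import TokenDoc

logger = logging.getLogger(__name__)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTMLayer:
    """One batched LSTM layer over padded, masked sequences.

    Gate order in the packed weight matrices is (input, forget, output,
    candidate). Padded steps carry hidden and cell state through
    unchanged, so the final state is the state at each sequence's true
    last step.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        H = d_hidden
        lim_x = np.sqrt(6.0 / (d_in + 4 * H))
        lim_h = np.sqrt(6.0 / (H + 4 * H))
        self.Wx = rng.uniform(-lim_x, lim_x, size=(d_in, 4 * H))
        self.Wh = rng.uniform(-lim_h, lim_h, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.H = H

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x: (B, T, D); mask: (B, T) in {0,1}. Returns (h_last, cache)."""
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            xt = x[:, t]
            m = mask[:, t][:, None]
            g = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(g[:, :H])
            f = _sigmoid(g[:, H : 2 * H])
            o = _sigmoid(g[:, 2 * H : 3 * H])
            u = np.tanh(g[:, 3 * H :])
            c_new = f * c + i * u
            h_new = o * np.tanh(c_new)
            steps.append((xt, h, c, i, f, o, u, c_new, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
        return h, steps

    def backward(self, dh_last: np.ndarray, steps) -> tuple[list[np.ndarray], np.ndarray]:
        """Returns ([dWx, dWh, db], dx) given the gradient at the final state."""
        H = self.H
        B = dh_last.shape[0]
        T = len(steps)
        d_in = self.Wx.shape[0]
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros((B, T, d_in))
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, o, u, c_new, m = steps[t]
            dh_new = m * dh
            dh_carry = (1 - m) * dh
            dc_new = m * dc
            dc_carry = (1 - m) * dc
            tc = np.tanh(c_new)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc * tc)
            di = dc_new * u
            df = dc_new * c_prev
            du = dc_new * i
            dc = dc_new * f + dc_carry
            dg = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), du * (1 - u * u)],
                axis=1,
            )
            dWx += xt.T @ dg
            dWh += h_prev.T @ dg
            db += dg.sum(axis=0)
            dx[:, t] = dg @ self.Wx.T
            dh = dg @ self.Wh.T + dh_carry
        return [dWx, dWh, db], dx


@dataclass
class RNNSpec:
    """Hyperparameters of the hierarchical LSTM classifier."""

    word_hidden: int = 64
    sent_hidden: int = 64
    epochs: int = 20
    batch: int = 32
    lr: float = 1e-3
    seed: int = 0
    max_tokens: int = 60  # per-sentence truncation, bounds padding cost
    max_sentences: int = 30
    kind: str = field(default="rnn", init=False)

    def complexity(self) -> float:
        return float(self.word_hidden * self.sent_hidden)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class HierarchicalLSTM:
    """Word-level then sentence-level LSTM with a logistic output head."""

    def __init__(self, emb: EmbeddingFile, spec: RNNSpec):
        self.emb = emb
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.word_lstm = LSTMLayer(emb.d, spec.word_hidden, rng)
        self.sent_lstm = LSTMLayer(spec.word_hidden, spec.sent_hidden, rng)
        lim = np.sqrt(6.0 / (spec.sent_hidden + 1))
        self.w_out = rng.uniform(-lim, lim, size=spec.sent_hidden)
        self.b_out = np.zeros(1)
        self._rng = rng

    # -- document encoding ------------------------------------------------

    def _embed_doc(self, doc: TokenDoc) -> list[np.ndarray]:
        """Doc as a list of (T, d) sentence matrices of frozen word vectors."""
        sents = []
        for sent in doc.sentences[: self.spec.max_sentences]:
            vecs = [self.emb.vector(t) for t in sent[: self.spec.max_tokens] if t in self.emb]
            if vecs:
                sents.append(np.stack(vecs))
        if not sents:  # fully out-of-vocabulary document
            sents = [np.zeros((1, self.emb.d))]
        return sents

    def _forward_batch(self, embedded: list[list[np.ndarray]]):
        B = len(embedded)
        Hw = self.spec.word_hidden
        # flatten sentences across the batch for one padded word-level pass
        flat = [s for doc in embedded for s in doc]
        owners = [bi for bi, doc in enumerate(embedded) for _ in doc]
        S = len(flat)
        Tmax = max(s.shape[0] for s in flat)
        x = np.zeros((S, Tmax, self.emb.d))
        xmask = np.zeros((S, Tmax))
        for si, s in enumerate(flat):
            x[si, : s.shape[0]] = s
            xmask[si, : s.shape[0]] = 1.0
        sent_vecs, word_cache = self.word_lstm.forward(x, xmask)

        Smax = max(sum(1 for o in owners if o == bi) for bi in range(B))
        sx = np.zeros((B, Smax, Hw))
        smask = np.zeros((B, Smax))
        slot = [0] * B
        placement = []  # (flat sentence index) -> (doc, slot)
        for si, bi in enumerate(owners):
            sx[bi, slot[bi]] = sent_vecs[si]
            smask[bi, slot[bi]] = 1.0
            placement.append((bi, slot[bi]))
            slot[bi] += 1
        doc_vecs, sent_cache = self.sent_lstm.forward(sx, smask)
        logits = doc_vecs @ self.w_out + self.b_out[0]
        cache = (word_cache, sent_cache, doc_vecs, placement, S)
        return logits, cache

    def _backward_batch(self, dlogits: np.ndarray, cache):
        word_cache, sent_cache, doc_vecs, placement, S = cache
        dw_out = doc_vecs.T @ dlogits
        db_out = np.array([dlogits.sum()])
        ddoc = np.outer(dlogits, self.w_out)
        sent_grads, dsx = self.sent_lstm.backward(ddoc, sent_cache)
        dsent_vecs = np.zeros((S, self.spec.word_hidden))
        for si, (bi, sl) in enumerate(placement):
            dsent_vecs[si] = dsx[bi, sl]
        word_grads, _ = self.word_lstm.backward(dsent_vecs, word_cache)
        return word_grads + sent_grads + [dw_out, db_out]

    # -- training / inference ---------------------------------------------

    def fit(self, docs: list[TokenDoc], y: np.ndarray) -> "HierarchicalLSTM":
        if not docs:
            raise ValueError("empty training corpus")
        y = np.asarray(y, dtype=float)
        covered = sum(any(t in self.emb for t in d.tokens()) for d in docs)
        if covered < 0.9 * len(docs):
            logger.warning(
                "embeddings cover only %d/%d documents (>=90%% expected)",
                covered,
                len(docs),
            )
        embedded = [self._embed_doc(d) for d in docs]
        params = self.word_lstm.params() + self.sent_lstm.params() + [self.w_out, self.b_out]
        opt = _Adam(params, self.spec.lr)
        n = len(docs)
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.spec.batch):
                idx = order[start : start + self.spec.batch]
                batch = [embedded[i] for i in idx]
                yb = y[idx]
                logits, cache = self._forward_batch(batch)
                p = _sigmoid(logits)
                dlogits = (p - yb) / len(idx)
                grads = self._backward_batch(dlogits, cache)
                opt.step(grads)
        return self

    def predict_proba(self, docs: list[TokenDoc], batch: int = 64) -> np.ndarray:
        out = np.empty(len(docs))
        embedded = [self._embed_doc(d) for d in docs]
        for start in range(0, len(docs), batch):
            logits, _ = self._forward_batch(embedded[start : start + batch])
            out[start : start + len(logits)] = _sigmoid(logits)
        return out
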