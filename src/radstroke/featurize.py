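"""Featurization of token documents: bag-of-words, tf-idf, document embeddings.

The vocabulary (with document frequencies) is always fitted on the training
split only; tokens unseen at fit time are dropped at transform time. The
tf-idf dialect is the smoothed form

    idf(t) = ln((1 + N) / (1 + df(t))) + 1

which keeps every weight at or above the raw term frequency and never
divides by zero for unseen tokens. A document embedding is the elementwise
sum of the word vectors of its in-vocabulary tokens.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EmbeddingFile
from .preprocess import TokenDoc


@dataclass
class Vocabulary:
    """Token -> column map plus training-corpus document frequencies."""

    index: dict[str, int]
    df: dict[str, int]
    n_docs: int

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def tokens(self) -> list[str]:
        return sorted(self.index, key=self.index.get)

    def idf(self) -> np.ndarray:
        """Smoothed inverse document frequency, aligned with column order."""
        df = np.array([self.df[t] for t in self.tokens], dtype=float)
        return np.log((1.0 + self.n_docs) / (1.0 + df)) + 1.0


@dataclass
class FeatureMatrix:
    """Reports-by-features numeric table with a kind tag."""

    report_ids: list[str]
    values: np.ndarray
    kind: str  # bow | tfidf | docvec
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.report_ids):
            raise ValueError("values must align row-wise with report_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        cols = self.feature_names or [f"f{i}" for i in range(self.values.shape[1])]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "report_id", self.report_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"report_id": str})
        ids = df.pop("report_id").tolist()
        return cls(ids, df.to_numpy(dtype=float), kind, feature_names=list(df.columns))


def fit_vocabulary(docs: list[TokenDoc], min_df: int = 1, allow_empty: bool = False) -> Vocabulary:
    """Build the training vocabulary: tokens with df >= min_df, columns lexicographic."""
    if not docs:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    df_counts: dict[str, int] = {}
    for doc in docs:
        for tok in set(doc.tokens()):
            df_counts[tok] = df_counts.get(tok, 0) + 1
    kept = sorted(t for t, c in df_counts.items() if c >= min_df)
    if not kept and not allow_empty:
        raise ValueError(f"no token reaches min_df={min_df} over {len(docs)} documents")
    return Vocabulary(
        index={t: i for i, t in enumerate(kept)},
        df={t: df_counts[t] for t in kept},
        n_docs=len(docs),
    )


def bow_vector(doc: TokenDoc, vocab: Vocabulary) -> np.ndarray:
    """Absolute token counts over the vocabulary; OOV tokens are ignored."""
    v = np.zeros(len(vocab), dtype=float)
    for tok in doc.tokens():
        j = vocab.index.get(tok)
        if j is not None:
            v[j] += 1
    return v


def bow_matrix(docs: list[TokenDoc], vocab: Vocabulary) -> FeatureMatrix:
    values = np.stack([bow_vector(d, vocab) for d in docs]) if docs else np.zeros((0, len(vocab)))
    return FeatureMatrix(
        [d.report_id for d in docs], values, "bow", feature_names=vocab.tokens
    )


def tfidf_transform(docs: list[TokenDoc], vocab: Vocabulary, l2_normalize: bool = False) -> FeatureMatrix:
    """tf * smoothed idf; no row normalization unless requested."""
    counts = bow_matrix(docs, vocab)
    values = counts.values * vocab.idf()[np.newaxis, :]
    if l2_normalize:
        norms = np.linalg.norm(values, axis=1, keepdims=True)
        np.divide(values, norms, out=values, where=norms > 0)
    return FeatureMatrix(counts.report_ids, values, "tfidf", feature_names=vocab.tokens)


def doc_embedding(doc: TokenDoc, emb: EmbeddingFile) -> np.ndarray:
    """Sum of word vectors of in-vocabulary tokens; zero vector if none."""
    if len(emb) == 0:
        raise ValueError("empty embedding file")
    v = np.zeros(emb.d, dtype=float)
    for tok in doc.tokens():
        if tok in emb:
            v += emb.vector(tok)
    return v


def doc_embedding_matrix(docs: list[TokenDoc], emb: EmbeddingFile) -> FeatureMatrix:
    values = np.stack([doc_embedding(d, emb) for d in docs]) if docs else np.zeros((0, emb.d))
    return FeatureMatrix(
        [d.report_id for d in docs],
        values,
        "docvec",
        feature_names=[f"e{i}" for i in range(emb.d)],
    )
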