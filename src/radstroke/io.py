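"""Readers and writers for every external format the pipeline touches.

Reports and labels travel as CSV, word embeddings as either a
self-describing CSV (header ``token,d1,...,dN``) or GloVe-style
space-separated text, and metrics as JSON/TSV elsewhere in the package.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCAN_TYPES = ("CT", "CTA", "MRI", "MRA")

REPORT_COLUMNS = ("report_id", "patient_id", "scan_type", "report_datetime", "text")
LABEL_COLUMNS = ("report_id", "stroke", "mca", "acute")


class CorpusFormatError(ValueError):
    """A file does not conform to its expected layout."""


@dataclass
class Report:
    """One imaging report: identity, scan modality, timestamp and free text."""

    report_id: str
    patient_id: str
    scan_type: str
    report_datetime: datetime | None
    raw_text: str

    def __post_init__(self) -> None:
        if self.scan_type not in SCAN_TYPES:
            raise CorpusFormatError(
                f"unknown scan_type {self.scan_type!r} for report "
                f"{self.report_id!r}; expected one of {SCAN_TYPES}"
            )


@dataclass
class LabelSet:
    """Three binary outcomes for one report: stroke presence, MCA territory, acuity."""

    report_id: str
    stroke: int
    mca: int
    acute: int

    def __post_init__(self) -> None:
        for name in ("stroke", "mca", "acute"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"label {name}={v!r} for {self.report_id!r} not in {{0,1}}")


@dataclass
class EmbeddingFile:
    """A vocabulary of tokens with one d-dimensional real vector per token."""

    tokens: list[str]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.tokens):
            raise ValueError("vectors must be an (n_tokens, d) matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("embedding tokens must be unique")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]


def read_reports(path: str | Path) -> list[Report]:
    """Load the report table, dropping rows with empty text.

    Rows whose ``text`` field is empty or whitespace are skipped and the
    skip count is logged; a missing column or an unrecognized scan type is
    an error. Duplicate report ids are a hard error because they would
    corrupt train/test split bookkeeping downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing required column(s) {missing}")

    reports: list[Report] = []
    skipped = 0
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        text = str(row.text)
        if not text.strip():
            skipped += 1
            continue
        rid = str(row.report_id)
        if rid in seen:
            raise CorpusFormatError(f"{path}: duplicate report_id {rid!r}")
        seen.add(rid)
        when_raw = str(row.report_datetime).strip()
        when = pd.to_datetime(when_raw).to_pydatetime() if when_raw else None
        reports.append(
            Report(
                report_id=rid,
                patient_id=str(row.patient_id),
                scan_type=str(row.scan_type).strip().upper(),
                report_datetime=when,
                raw_text=text,
            )
        )
    if skipped:
        logger.info("read_reports(%s): skipped %d empty-text row(s)", path, skipped)
    return reports


def write_reports(reports: list[Report], path: str | Path) -> None:
    rows = [
        {
            "report_id": r.report_id,
            "patient_id": r.patient_id,
            "scan_type": r.scan_type,
            "report_datetime": r.report_datetime.isoformat() if r.report_datetime else "",
            "text": r.raw_text,
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, index=False)


def read_labels(path: str | Path, reports: list[Report]) -> list[LabelSet]:
    """Load the label table and join it against a report list.

    Label values must be 0/1. A row with ``mca=1`` or ``acute=1`` but
    ``stroke=0`` is accepted with a logged warning (labeling noise can
    produce it); reports with no label row are logged as unlabeled.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing required column(s) {missing}")

    labels: list[LabelSet] = []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = {}
        for name in ("stroke", "mca", "acute"):
            raw = getattr(row, name).strip()
            if raw not in ("0", "1"):
                raise ValueError(
                    f"{path}: row {i + 2}: label {name}={raw!r} not in {{0,1}}"
                )
            vals[name] = int(raw)
        ls = LabelSet(report_id=str(row.report_id), **vals)
        if ls.stroke == 0 and (ls.mca == 1 or ls.acute == 1):
            logger.warning(
                "label row for %r has mca/acute positive with stroke=0", ls.report_id
            )
        labels.append(ls)

    labeled_ids = {l.report_id for l in labels}
    unlabeled = [r.report_id for r in reports if r.report_id not in labeled_ids]
    if unlabeled:
        logger.info("read_labels(%s): %d report(s) unlabeled", path, len(unlabeled))
    return labels


def write_labels(labels: list[LabelSet], path: str | Path) -> None:
    rows = [
        {"report_id": l.report_id, "stroke": l.stroke, "mca": l.mca, "acute": l.acute}
        for l in labels
    ]
    pd.DataFrame(rows, columns=list(LABEL_COLUMNS)).to_csv(path, index=False)


def labels_frame(labels: list[LabelSet]) -> pd.DataFrame:
    """Labels as a DataFrame indexed by report_id."""
    return pd.DataFrame(
        {
            "stroke": [l.stroke for l in labels],
            "mca": [l.mca for l in labels],
            "acute": [l.acute for l in labels],
        },
        index=pd.Index([l.report_id for l in labels], name="report_id"),
    )


def write_embeddings(emb: EmbeddingFile, path: str | Path, dialect: str = "csv") -> None:
    """Write embeddings as CSV (``token,d1,...,dN`` header) or GloVe text.

    Values are written with 12 significant digits so a write/read
    round-trip preserves them to better than 1e-10 absolute error.
    In the space-separated dialect a token containing whitespace cannot be
    represented and is rejected; CSV quotes such tokens instead.
    """
    path = Path(path)
    d = emb.d
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["token"] + [f"d{i + 1}" for i in range(d)])
            for tok, vec in zip(emb.tokens, emb.vectors):
                writer.writerow([tok] + [f"{v:.12g}" for v in vec])
    elif dialect == "glove_text":
        with open(path, "w") as fh:
            for tok, vec in zip(emb.tokens, emb.vectors):
                if any(ch.isspace() for ch in tok):
                    raise ValueError(
                        f"token {tok!r} contains whitespace; not representable "
                        "in the space-separated dialect"
                    )
                fh.write(tok + " " + " ".join(f"{v:.12g}" for v in vec) + "\n")
    else:
        raise ValueError(f"unknown embedding dialect {dialect!r}")


def read_embeddings(path: str | Path, dialect: str = "csv") -> EmbeddingFile:
    """Read embeddings written by :func:`write_embeddings`.

    Ragged rows raise a format error naming the offending line; duplicate
    tokens keep the first occurrence with a logged warning.
    """
    path = Path(path)
    tokens: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    dupes = 0
    arity: int | None = None

    def _add(lineno: int, tok: str, vals: list[str]) -> None:
        nonlocal arity, dupes
        if arity is None:
            arity = len(vals)
        elif len(vals) != arity:
            raise CorpusFormatError(
                f"{path}: line {lineno}: expected {arity} values, got {len(vals)}"
            )
        if tok in seen:
            dupes += 1
            return
        seen.add(tok)
        tokens.append(tok)
        rows.append([float(v) for v in vals])

    if dialect == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or not header or header[0] != "token":
                raise CorpusFormatError(f"{path}: expected header starting with 'token'")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                _add(lineno, row[0], row[1:])
    elif dialect == "glove_text":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                _add(lineno, parts[0], parts[1:])
    else:
        raise ValueError(f"unknown embedding dialect {dialect!r}")

    if dupes:
        logger.warning(
            "read_embeddings(%s): %d duplicate token(s), first occurrence kept",
            path,
            dupes,
        )
    if not tokens:
        raise CorpusFormatError(f"{path}: no embedding rows")
    return EmbeddingFile(tokens=tokens, vectors=np.array(rows, dtype=float))
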