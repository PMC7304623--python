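"""Text normalization for radiology reports.

Raw dictated reports carry boilerplate headers, separator art
("= = = = = ="), inconsistent casing and punctuation. Cleaning lowercases
the text, strips boilerplate and separators, maps punctuation to spaces
(sentence-ending ``.!?`` are kept until sentence splitting), and collapses
whitespace. Common multi-word medical phrases are then merged into single
n-gram tokens ("middle cerebral artery" -> "middlecerebralartery") so that
downstream featurizers treat them as one unit.

Stop words are retained: tf-idf is the down-weighting mechanism for them.
Negation is deliberately not parsed; classifiers must learn it from context.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .io import Report

#: Site-specific boilerplate is configuration, not a constant; these defaults
#: cover common header/footer lines in dictated reports.
DEFAULT_BOILERPLATE_PATTERNS: tuple[str, ...] = (
    r"(?im)^\s*(?:name|mrn|dob|accession|exam(?:\s+(?:date|number))?|referring\s+physician|ordering\s+provider)\s*:[^\n]*$",
    r"(?im)^\s*electronically\s+signed\s+by[^\n]*$",
    r"(?im)^\s*(?:dictated|transcribed)\s+by[^\n]*$",
    r"(?im)^\s*report\s+(?:status|number)\s*:[^\n]*$",
)

# Runs of the same separator character (optionally space-separated), length >= 3.
_SEPARATOR_RUN = re.compile(r"([=\-_*~#+])(?:\s*\1){2,}")
_NON_TOKEN = re.compile(r"[^a-z0-9\s.!?]")
_SPACE_BEFORE_TERM = re.compile(r"\s+([.!?])")
_TERM_RUN = re.compile(r"([.!?])[\s.!?]*[.!?]")
_WS = re.compile(r"\s+")
_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")


@dataclass
class TokenDoc:
    """A preprocessed report: ordered sentences of lowercase tokens."""

    report_id: str
    sentences: list[list[str]]

    def tokens(self) -> list[str]:
        """All tokens in reading order, ignoring sentence boundaries."""
        return [t for sent in self.sentences for t in sent]


class PhraseLexicon:
    """Ordered (phrase -> merged token) rules, matched longest-first."""

    def __init__(self, rules: dict[str, str] | list[tuple[str, str]]):
        items = list(rules.items()) if isinstance(rules, dict) else list(rules)
        for phrase, merged in items:
            if " " in merged:
                raise ValueError(f"merged token {merged!r} contains a space")
        # longest phrase (in words, then chars) first so prefixes never win
        self._rules = sorted(
            items, key=lambda pm: (-len(pm[0].split()), -len(pm[0]), pm[0])
        )
        self._patterns = [
            (re.compile(r"(?<![a-z0-9])" + re.escape(p) + r"(?![a-z0-9])"), m)
            for p, m in self._rules
        ]

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhraseLexicon":
        """Two-column CSV: phrase, merged_token (no header required)."""
        rules: list[tuple[str, str]] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "phrase":
                    continue
                rules.append((row[0].strip().lower(), row[1].strip().lower()))
        return cls(rules)

    @classmethod
    def default(cls) -> "PhraseLexicon":
        phrases = [
            "middle cerebral artery territory",
            "middle cerebral artery",
            "anterior cerebral artery",
            "posterior cerebral artery",
            "internal carotid artery",
            "external carotid artery",
            "basilar artery",
            "vertebral artery",
            "posterior inferior cerebellar artery",
            "anterior inferior cerebellar artery",
            "superior cerebellar artery",
            "anterior communicating artery",
            "posterior communicating artery",
            "mca territory",
            "pca territory",
            "aca territory",
            "diffusion restriction",
            "restricted diffusion",
            "diffusion weighted imaging",
            "apparent diffusion coefficient",
            "adc hypointensity",
            "grey white matter",
            "gray white matter",
            "grey white differentiation",
            "gray white differentiation",
            "t2 prolongation",
            "flair hyperintensity",
            "sulcal effacement",
            "midline shift",
            "mass effect",
            "hemorrhagic transformation",
            "subarachnoid hemorrhage",
            "intracranial hemorrhage",
            "small vessel disease",
            "microvascular ischemic changes",
            "watershed infarct",
        ]
        return cls([(p, p.replace(" ", "")) for p in phrases])


def clean_text(raw: str, boilerplate_patterns: tuple[str, ...] | list[str] = DEFAULT_BOILERPLATE_PATTERNS) -> str:
    """Normalize raw report text.

    Removes boilerplate lines matching the configured patterns and
    separator runs such as ``= = = = = =``, lowercases, replaces
    punctuation with spaces (keeping sentence terminators attached to the
    preceding word), and collapses whitespace. Idempotent; may return "".
    """
    text = raw
    for pat in boilerplate_patterns:
        text = re.sub(pat, " ", text)
    text = _SEPARATOR_RUN.sub(" ", text)
    text = text.lower()
    # punctuation -> space (not deletion) so "stroke.Impression" style
    # dictation artifacts cannot fuse adjacent words
    text = _NON_TOKEN.sub(" ", text)
    text = _SPACE_BEFORE_TERM.sub(r"\1", text)
    text = _TERM_RUN.sub(r"\1", text)
    # a terminator glues to the word before it but never to the word after
    text = re.sub(r"([.!?])(?=[a-z0-9])", r"\1 ", text)
    text = _WS.sub(" ", text).strip()
    # a terminator with no preceding word carries no sentence
    text = re.sub(r"(?:(?<=^)|(?<= ))[.!?]+\s*", "", text).strip()
    return text


def merge_phrases(text: str, lexicon: PhraseLexicon) -> str:
    """Replace every lexicon phrase with its merged token, longest first."""
    for pattern, merged in lexicon._patterns:
        text = pattern.sub(merged, text)
    return text


def split_sentences(text: str) -> list[str]:
    """Split cleaned text on sentence terminators; drop empty sentences."""
    parts = _SENT_SPLIT.split(text)
    out = []
    for part in parts:
        stripped = part.strip().strip(".!?").strip()
        if stripped:
            out.append(stripped)
    return out


def tokenize(sentence: str) -> list[str]:
    """Whitespace tokenization of one cleaned sentence."""
    return sentence.split()


def preprocess_report(
    report: Report | str,
    lexicon: PhraseLexicon | None = None,
    boilerplate_patterns: tuple[str, ...] | list[str] = DEFAULT_BOILERPLATE_PATTERNS,
    report_id: str = "",
) -> TokenDoc:
    """Full cleaning pipeline: clean, merge phrases, split, tokenize."""
    if lexicon is None:
        lexicon = PhraseLexicon.default()
    if isinstance(report, Report):
        raw, rid = report.raw_text, report.report_id
    else:
        raw, rid = report, report_id
    text = merge_phrases(clean_text(raw, boilerplate_patterns), lexicon)
    sentences = [tokenize(s) for s in split_sentences(text)]
    return TokenDoc(report_id=rid, sentences=[s for s in sentences if s])


def preprocess_corpus(
    reports: list[Report],
    lexicon: PhraseLexicon | None = None,
    boilerplate_patterns: tuple[str, ...] | list[str] = DEFAULT_BOILERPLATE_PATTERNS,
) -> list[TokenDoc]:
    if lexicon is None:
        lexicon = PhraseLexicon.default()
    return [preprocess_report(r, lexicon, boilerplate_patterns) for r in reports]
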