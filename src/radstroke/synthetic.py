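"""Synthetic neuroradiology reports and embedding corpora with known labels.

Real stroke imaging reports are protected health information, so every
stage of the pipeline is exercised on generated narrative reports that
deliberately reproduce the hard cases of the task: affirmative acute
strokes inside and outside the middle-cerebral-artery territory, chronic
infarcts (stroke present, acuity absent), negated stroke language in
negative reports ("no evidence of acute infarct"), references to prior
imaging, and chronic microvascular change descriptions that mention
ischemia without an infarct. Acuity is therefore measurably harder to
classify than presence, mirroring clinical labeling experience.

Defaults mirror a realistic derivation cohort: 1,359 reports with stroke
prevalence 0.68, MCA-territory fraction 0.38 and acute fraction 0.56 among
strokes, and a roughly 65:35 CT/CTA to MRI/MRA mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .io import LabelSet, Report

_SIDES = ("left", "right")
_MCA_TERRITORIES = (
    "{side} middle cerebral artery territory",
    "{side} mca territory",
)
_NON_MCA_TERRITORIES = (
    "{side} posterior cerebral artery territory",
    "{side} anterior cerebral artery territory",
    "{side} cerebellar hemisphere",
    "{side} thalamus",
    "pons",
    "{side} occipital lobe",
)
_ACUTE_NOUN = ("acute infarct", "acute infarction", "acute ischemic stroke", "acute ischemia")
# wording shared by recent and old strokes of uncertain timing: carries no
# acuity signal, only presence signal
_INDETERMINATE_NOUN = (
    "subacute infarct",
    "subacute infarction",
    "evolving infarct",
    "infarct of indeterminate age",
)
_CHRONIC_NOUN = ("chronic infarct", "old infarct", "remote infarction", "chronic lacunar infarct")
_INDICATIONS = (
    "left sided weakness",
    "right sided weakness",
    "aphasia and facial droop",
    "altered mental status",
    "dizziness and gait instability",
    "fall with head strike",
    "worst headache of life",
    "slurred speech",
)
_STROKE_INDICATIONS = (
    "evaluate for acute stroke",
    "code stroke activation",
    "rule out ischemic stroke",
)
_NEGATIONS = (
    "No evidence of acute infarct.",
    "No acute infarct or hemorrhage identified.",
    "No restricted diffusion to suggest acute ischemic stroke.",
    "No evidence of acute territorial infarction.",
)
_BENIGN_FINDINGS = (
    "The ventricles and sulci are normal in size and configuration.",
    "No midline shift or mass effect.",
    "No acute intracranial hemorrhage.",
    "The visualized paranasal sinuses are clear.",
    "Gray white differentiation is preserved.",
)
# hard-case sentences that bleed infarct/territory vocabulary into reports
# regardless of their label: prior-scan references and microvascular change
_DISTRACTORS = (
    "Scattered chronic microvascular ischemic changes in the periventricular white matter.",
    "Patient has a reported history of prior stroke.",
    "Prior examination reportedly demonstrated an infarct in the {terr}, not visualized on the current study.",
    "Comparison is made to outside imaging which described a {terr} infarct.",
    "Chronic small vessel disease, unchanged from prior examination.",
)
_CT_ACUTE_FINDINGS = (
    "There is a hypodensity involving the {terr} with loss of gray white differentiation consistent with {noun}.",
    "Sulcal effacement and early hypoattenuation in the {terr} compatible with {noun}.",
)
_MR_ACUTE_FINDINGS = (
    "There is restricted diffusion with apparent diffusion coefficient hypointensity in the {terr} consistent with {noun}.",
    "Diffusion weighted imaging demonstrates {noun} in the {terr}.",
)
_CHRONIC_FINDINGS = (
    "There is encephalomalacia and gliosis in the {terr} consistent with {noun}.",
    "Volume loss with cystic encephalomalacia in the {terr} compatible with {noun}.",
    "A {noun} is seen in the {terr} with associated t2 prolongation and volume loss.",
)
_INDETERMINATE_FINDINGS = (
    "There is a {noun} in the {terr}.",
    "Findings in the {terr} are compatible with {noun}.",
    "An area of signal abnormality in the {terr} represents {noun}.",
)


@dataclass
class GeneratorConfig:
    """Knobs of the labeled-report generator; probabilities in [0,1]."""

    n_reports: int = 1359
    p_stroke: float = 0.68
    p_mca_given_stroke: float = 0.38
    p_acute_given_stroke: float = 0.56
    negation_rate: float = 0.5
    distractor_rate: float = 0.3
    label_noise: float = 0.02
    template_jitter: float = 0.3
    seed: int = 0
    reports_per_patient: float = 4.5  # mean; patients drawn geometrically

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        for name in (
            "p_stroke",
            "p_mca_given_stroke",
            "p_acute_given_stroke",
            "negation_rate",
            "distractor_rate",
            "label_noise",
            "template_jitter",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class SyntheticCorpusSpec:
    """Plain-text corpus with planted synonym pairs in identical contexts."""

    n_docs: int = 400
    vocab_size: int = 60
    synonym_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("infarct", "infarction"),
            ("hemorrhage", "bleed"),
            ("edema", "swelling"),
        ]
    )
    sentences_per_doc: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [t for pair in self.synonym_pairs for t in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("synonym pairs must be disjoint")
        if self.vocab_size <= 2 * len(self.synonym_pairs):
            raise ValueError("vocab_size must exceed twice the number of pairs")


def _choice(rng: np.random.Generator, options, jitter: float):
    """First option is canonical; alternatives appear at the jitter rate."""
    if len(options) == 1 or rng.random() >= jitter:
        return options[0]
    return options[1 + rng.integers(len(options) - 1)]


def _territory(rng, mca: bool, jitter: float) -> str:
    side = _SIDES[rng.integers(2)]
    pool = _MCA_TERRITORIES if mca else _NON_MCA_TERRITORIES
    return _choice(rng, pool, max(jitter, 0.5)).format(side=side)


def _distractor(rng, jitter: float) -> str:
    s = _DISTRACTORS[rng.integers(len(_DISTRACTORS))]
    if "{terr}" in s:
        s = s.format(terr=_territory(rng, rng.random() < 0.4, jitter))
    return s


def generate_reports(cfg: GeneratorConfig | None = None) -> tuple[list[Report], list[LabelSet]]:
    """Seeded labeled report corpus.

    Labels derive from the generating template before ``label_noise`` is
    applied, so pre-noise they satisfy mca=1 => stroke=1 and
    acute=1 => stroke=1. Negated stroke sentences appear only in
    stroke-negative reports (at ``negation_rate``); chronic-infarct
    templates yield stroke=1, acute=0; distractor sentences mentioning
    stroke history or microvascular ischemia blur the lexical signal at
    ``distractor_rate``.
    """
    if cfg is None:
        cfg = GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    reports: list[Report] = []
    labels: list[LabelSet] = []
    t0 = datetime(2016, 1, 3, 8, 15)

    patient_no = 0
    remaining_for_patient = 0
    for i in range(cfg.n_reports):
        if remaining_for_patient == 0:
            patient_no += 1
            remaining_for_patient = int(rng.geometric(1.0 / cfg.reports_per_patient))
        remaining_for_patient -= 1

        is_mr = rng.random() < 0.35
        if is_mr:
            scan = "MRA" if rng.random() < 0.25 else "MRI"
        else:
            scan = "CTA" if rng.random() < 0.25 else "CT"

        stroke = int(rng.random() < cfg.p_stroke)
        mca = int(stroke and rng.random() < cfg.p_mca_given_stroke)
        acute = int(stroke and rng.random() < cfg.p_acute_given_stroke)

        sentences: list[str] = []
        # stroke-code indications precede negative scans just as often
        if rng.random() < 0.3:
            indication = _STROKE_INDICATIONS[rng.integers(len(_STROKE_INDICATIONS))]
        else:
            indication = _INDICATIONS[rng.integers(len(_INDICATIONS))]
        header = (
            f"EXAM: {scan} head.\nCLINICAL HISTORY: {indication}.\n"
            "= = = = = = = = = =\nFINDINGS:"
        )

        if stroke:
            terr = _territory(rng, bool(mca), cfg.template_jitter)
            # ~35% of strokes are described with timing-neutral wording
            # ("subacute", "indeterminate age"), regardless of the true
            # acuity label: radiologists often cannot date an infarct
            indeterminate = rng.random() < 0.35
            if indeterminate:
                noun = _choice(rng, _INDETERMINATE_NOUN, max(cfg.template_jitter, 0.5))
                pool = _INDETERMINATE_FINDINGS
            elif acute:
                noun = _choice(rng, _ACUTE_NOUN, cfg.template_jitter)
                pool = _MR_ACUTE_FINDINGS if is_mr else _CT_ACUTE_FINDINGS
            else:
                noun = _choice(rng, _CHRONIC_NOUN, cfg.template_jitter)
                pool = _CHRONIC_FINDINGS
            sentences.append(_choice(rng, pool, cfg.template_jitter).format(terr=terr, noun=noun))
            if rng.random() < cfg.distractor_rate:
                sentences.append(_distractor(rng, cfg.template_jitter))
            impression = f"IMPRESSION: {noun.capitalize()} in the {terr}."
        else:
            if rng.random() < cfg.negation_rate:
                sentences.append(_NEGATIONS[rng.integers(len(_NEGATIONS))])
            if rng.random() < cfg.distractor_rate:
                sentences.append(_distractor(rng, cfg.template_jitter))
            impression = "IMPRESSION: No acute intracranial abnormality."

        n_benign = 1 + int(rng.integers(3))
        for j in rng.choice(len(_BENIGN_FINDINGS), size=n_benign, replace=False):
            sentences.append(_BENIGN_FINDINGS[j])

        text = header + " " + " ".join(sentences) + "\n" + impression
        reports.append(
            Report(
                report_id=f"R{i:05d}",
                patient_id=f"P{patient_no:04d}",
                scan_type=scan,
                report_datetime=t0 + timedelta(hours=int(rng.integers(6, 30)) + 26 * i),
                raw_text=text,
            )
        )

        noisy = [stroke, mca, acute]
        for k in range(3):
            if rng.random() < cfg.label_noise:
                noisy[k] = 1 - noisy[k]
        labels.append(
            LabelSet(report_id=f"R{i:05d}", stroke=noisy[0], mca=noisy[1], acute=noisy[2])
        )
    return reports, labels


def generate_embedding_corpus(spec: SyntheticCorpusSpec | None = None) -> list[str]:
    """Plain-text documents with planted synonym pairs.

    Each synonym pair owns a small set of context tokens; whenever one of
    its sentence frames is generated, the slot is filled by either pair
    member with equal probability, so the two members see identical
    context distributions. Background sentences draw tokens from a
    Zipf-like distribution over the remaining vocabulary.
    """
    if spec is None:
        spec = SyntheticCorpusSpec()
    rng = np.random.default_rng(spec.seed)
    pair_tokens = {t for pair in spec.synonym_pairs for t in pair}
    n_bg = spec.vocab_size - len(pair_tokens)
    background = [f"w{k:02d}" for k in range(n_bg)]
    # Zipf-ish weights over background tokens
    weights = 1.0 / np.arange(1, n_bg + 1)
    weights /= weights.sum()

    # each pair gets a disjoint slice of context tokens
    per_pair = max(3, n_bg // (2 * max(1, len(spec.synonym_pairs))))
    contexts = [
        background[k * per_pair : (k + 1) * per_pair]
        for k in range(len(spec.synonym_pairs))
    ]

    docs: list[str] = []
    for _ in range(spec.n_docs):
        sents = []
        for _ in range(spec.sentences_per_doc):
            if spec.synonym_pairs and rng.random() < 0.5:
                k = int(rng.integers(len(spec.synonym_pairs)))
                member = spec.synonym_pairs[k][int(rng.integers(2))]
                ctx = contexts[k] if contexts[k] else background[:3]
                picks = rng.choice(len(ctx), size=min(4, len(ctx)), replace=False)
                words = [ctx[picks[0]], ctx[picks[1]], member] + [
                    ctx[q] for q in picks[2:]
                ]
            else:
                n_words = 4 + int(rng.integers(4))
                words = list(rng.choice(background, size=n_words, p=weights))
            sents.append(" ".join(words) + ".")
        docs.append(" ".join(sents))
    return docs
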