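"""Synthetic paired study dictionaries with known ground truth.

Real cohort data dictionaries are usually access-restricted, so this module
generates two dictionaries that mimic their statistical character: a smaller
source study and a larger target study whose variables describe overlapping
clinical concepts (demographics, anthropometrics, questionnaire items, costs,
time-to-event) under divergent naming conventions.  Matched variables derive
from the same concept through independent noise channels (synonym swaps,
word drops, token moves, abbreviation); unmatched target variables come from
held-out concepts, so negatives are plausible but unambiguous.  Defaults are
calibrated to the descriptive statistics of published cohort dictionaries:
source labels are longer than target labels (≈11 vs ≈8.5 words), derivation
rules are mostly missing on the source side (≈70%) but mostly present on the
target side (≈10% missing), and about a fifth of matched sources have 2-3
true targets.

Everything is driven by one seed; the same config always produces
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dictionary import (
    LongFormatSpec,
    MatchTable,
    StudyDictionary,
    VariableRecord,
)
from .errors import ValidationError

# --------------------------------------------------------------------------
# concept inventory: five clinical categories, phrase-level synonym and
# abbreviation fixtures (static, offline)

CATEGORIES = (
    "demographics",
    "anthropometric",
    "questionnaire",
    "cost",
    "time_to_event",
)

_BASES: dict[str, tuple[str, ...]] = {
    "demographics": (
        "sex", "age at enrollment", "marital status", "education level",
        "living area", "ethnic group", "employment status",
        "household size", "caregiver relationship",
    ),
    "anthropometric": (
        "body mass index", "body weight", "standing height",
        "systolic blood pressure", "diastolic blood pressure",
        "heart rate", "waist circumference", "body temperature",
    ),
    "questionnaire": (
        "orientation to time", "orientation to place", "word recall",
        "attention and calculation", "language naming", "sentence writing",
        "figure copying", "delayed memory recall", "dressing ability",
        "feeding ability", "walking ability", "toileting ability",
        "shopping ability", "telephone use",
    ),
    "cost": (
        "caregiver indirect cost", "outpatient care cost",
        "hospitalization cost", "medication cost", "community care cost",
        "total societal cost", "informal care time cost",
    ),
    "time_to_event": (
        "time to death", "time to institutionalization",
        "time to study discontinuation", "time to dementia progression",
    ),
}

# qualifier token sets are mutually non-nested (after stop-word removal and
# stemming) so distinct concepts never tie at a perfect token-set score
_QUALIFIERS = (
    "at baseline", "at the visit", "change since enrollment",
    "over the study period", "per month", "total score",
    "caregiver reported", "at month eighteen",
)

# divergent naming usually keeps the construct's head noun, so most synonym
# pairs share a content token; a few fully disjoint renamings (sex/gender)
# are kept for realism
SYNONYMS: dict[str, tuple[str, ...]] = {
    "sex": ("gender",),
    "body mass index": ("mass index quetelet",),
    "body weight": ("weight measurement",),
    "living area": ("living location",),
    "marital status": ("marital state",),
    "education level": ("education years completed",),
    "heart rate": ("pulse rate",),
    "medication cost": ("medication expenditure",),
    "time to death": ("months to death",),
    "word recall": ("word registration",),
    "delayed memory recall": ("recall after delay",),
    "hospitalization cost": ("hospitalization inpatient cost",),
    "age at enrollment": ("age at study entry",),
    "employment status": ("employment situation",),
}

ABBREVIATIONS: dict[str, str] = {
    "body mass index": "BMI",
    "systolic blood pressure": "SBP",
    "diastolic blood pressure": "DBP",
    "heart rate": "HR",
    "time to death": "TTD",
    "time to institutionalization": "TTI",
    "education level": "EDU",
    "total societal cost": "TSC",
}

_SOURCE_PREFIX: dict[str, tuple[str, ...]] = {
    "demographics": ("subject characteristic",),
    "anthropometric": ("vital sign result numeric",),
    "questionnaire": ("item result numeric correct response to",),
    "cost": ("cost item result numeric",),
    "time_to_event": ("time to event result numeric",),
}

_SHEETS: dict[str, tuple[str, str]] = {
    # category -> (source sheet description, target sheet description)
    "demographics": ("Demographics Relationship",
                     "Subject Level Analysis Dataset"),
    "anthropometric": ("Vitals", "Vital Signs per visit"),
    "questionnaire": ("Cognitive and Functional Exam",
                      "Cognitive and Functional Assessment per visit"),
    "cost": ("Cost Caregiver Indirect Nonmedical",
             "Total Cost up to the visit per visit"),
    "time_to_event": ("Time to Event", "Subject Level Analysis Dataset"),
}

_FILLER = (
    "recorded", "during", "the", "study", "assessment", "observed",
    "value", "derived", "standard", "analysis", "numeric", "result",
)

_RULE_TEMPLATES = (
    "derived from the {base} recorded at each scheduled visit",
    "values one equals yes two equals no and nine equals unknown",
    "computed as the {qual} of all available {base} measurements",
    "missing values are coded as nine nine nine and excluded from analysis",
    "based on the {base} reported by the primary caregiver",
    "collected with the standard case report form during the {qual} window",
    "sum of the item scores contributing to the {base} component",
    "set to null when the participant discontinued before the visit",
)


@dataclass(frozen=True)
class LabelNoise:
    """Per-label probabilities of the four label corruption channels."""

    synonym: float = 0.60
    drop: float = 0.30
    shuffle: float = 0.25
    abbreviation: float = 0.35

    def validate(self) -> None:
        for name, p in vars(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"label_noise.{name} must be in [0,1]")


@dataclass(frozen=True)
class SynthConfig:
    """Shape and difficulty of the generated dictionary pair."""

    n_source: int = 60
    n_target: int = 240
    match_rate: float = 0.9
    multi_match_rate: float = 0.2
    label_noise: LabelNoise = field(default_factory=LabelNoise)
    rule_missing_src: float = 0.7
    rule_missing_tgt: float = 0.1
    rule_length_src: tuple[float, float] = (15.0, 10.0)
    rule_length_tgt: tuple[float, float] = (26.0, 15.0)
    label_words_src: float = 11.3
    label_words_tgt: float = 8.5
    n_sheets: int = 5
    seed: int = 7

    def validate(self) -> None:
        for name in ("match_rate", "multi_match_rate",
                     "rule_missing_src", "rule_missing_tgt"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")
        self.label_noise.validate()
        if self.n_target < self.n_source:
            raise ValidationError("n_target must be >= n_source")
        if self.n_sheets < 1:
            raise ValidationError("n_sheets must be >= 1")


@dataclass(frozen=True)
class _Concept:
    category: str
    base: str
    qualifier: str


def _build_concepts() -> list[_Concept]:
    out = []
    for cat in CATEGORIES:
        for base in _BASES[cat]:
            for qual in _QUALIFIERS:
                out.append(_Concept(cat, base, qual))
    return out


def _abbrev_name(base: str) -> str:
    return "".join(w[0] for w in base.split()).upper()


def _render_label(
    concept: _Concept,
    *,
    side: str,
    noise: LabelNoise,
    target_words: float,
    rng: np.random.Generator,
) -> str:
    if (noise.synonym == noise.drop == noise.shuffle
            == noise.abbreviation == 0.0):
        # zero-noise limit: both studies render the concept canonically,
        # so matched labels are identical by construction
        label = f"{concept.base} {concept.qualifier}"
        return label[0].upper() + label[1:]

    base = concept.base
    if rng.random() < noise.synonym and base in SYNONYMS:
        syns = SYNONYMS[base]
        base = syns[int(rng.integers(len(syns)))]
    if rng.random() < noise.abbreviation and concept.base in ABBREVIATIONS:
        abbr = ABBREVIATIONS[concept.base]
        # target dictionaries typically spell the construct out with the
        # abbreviation in parentheses; source dictionaries use it bare
        base = f"{base} ({abbr})" if side == "tgt" else abbr

    base_tokens = base.split()
    rest = concept.qualifier.split()
    if side == "src" and rng.random() < 0.85:
        rest = _SOURCE_PREFIX[concept.category][0].split() + rest

    # corruption spares the construct tokens: real studies rename and trim
    # qualifiers far more often than the construct itself
    if rng.random() < noise.shuffle and rest:
        i = int(rng.integers(len(rest)))
        tok = rest.pop(i)
        rest.insert(int(rng.integers(len(rest) + 1)), tok)
    if rng.random() < noise.drop and len(rest) > 1:
        rest.pop(int(rng.integers(len(rest))))

    if rng.random() < noise.shuffle:
        head, tail = rest[: len(rest) // 2], rest[len(rest) // 2 :]
    else:
        head, tail = [], rest
    tokens = head + base_tokens + tail
    min_keep = len(head) + len(base_tokens)
    want = max(3, int(round(rng.normal(target_words, 0.30 * target_words))))
    while len(tokens) < want:
        tokens.append(_FILLER[int(rng.integers(len(_FILLER)))])
    if len(tokens) > want:
        tokens = tokens[: max(want, min_keep)]
    label = " ".join(tokens)
    return label[0].upper() + label[1:]


def _render_rule(
    concept: _Concept,
    *,
    missing_p: float,
    length: tuple[float, float],
    rng: np.random.Generator,
) -> str:
    if rng.random() < missing_p:
        return ""
    mean, sd = length
    want = max(3, int(round(rng.normal(mean, sd))))
    order = rng.permutation(len(_RULE_TEMPLATES))
    clauses: list[str] = []
    total = 0
    for idx in order:
        clause = _RULE_TEMPLATES[int(idx)].format(
            base=concept.base, qual=concept.qualifier
        )
        clauses.append(clause)
        total += len(clause.split())
        if total >= want:
            break
    return "; ".join(clauses)


def _sheet_for(category: str, n_sheets: int, side: int) -> tuple[str, str]:
    idx = min(CATEGORIES.index(category), n_sheets - 1)
    cat = CATEGORIES[idx]
    desc = _SHEETS[cat][side]
    name = cat.upper()[:8] + ("_S" if side == 0 else "_T")
    return name, desc


def generate_paired_dictionaries(
    config: SynthConfig | None = None,
) -> tuple[StudyDictionary, StudyDictionary, MatchTable]:
    """Generate (source dictionary, target dictionary, ground truth).

    Matched variables are independent noisy renderings of shared concepts;
    distractor targets come from held-out concepts.  Fully deterministic in
    ``config.seed``.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    concepts = _build_concepts()
    order = rng.permutation(len(concepts))
    concepts = [concepts[i] for i in order]

    n_matched = int(round(config.match_rate * config.n_source))
    n_unmatched_src = config.n_source - n_matched
    if n_matched + n_unmatched_src > len(concepts):
        raise ValidationError("n_source exceeds the available concept pool")

    src_records: list[VariableRecord] = []
    tgt_records: list[VariableRecord] = []
    pairs: list[tuple[str, str]] = []
    used_names_src: set[str] = set()
    used_names_tgt: set[str] = set()

    def make_record(concept, side, index) -> VariableRecord:
        if side == "src":
            label = _render_label(concept, side="src", noise=config.label_noise,
                                  target_words=config.label_words_src, rng=rng)
            rule = _render_rule(concept, missing_p=config.rule_missing_src,
                                length=config.rule_length_src, rng=rng)
            sheet_name, sheet_desc = _sheet_for(concept.category,
                                                config.n_sheets, 0)
            name = f"{sheet_name[:3]}_{_abbrev_name(concept.base)}{index}"
            used = used_names_src
            study = "SRC"
        else:
            label = _render_label(concept, side="tgt", noise=config.label_noise,
                                  target_words=config.label_words_tgt, rng=rng)
            rule = _render_rule(concept, missing_p=config.rule_missing_tgt,
                                length=config.rule_length_tgt, rng=rng)
            sheet_name, sheet_desc = _sheet_for(concept.category,
                                                config.n_sheets, 1)
            name = f"{_abbrev_name(concept.base)}{index}"
            used = used_names_tgt
            study = "TGT"
        while name in used:
            name += "X"
        used.add(name)
        return VariableRecord(
            study_id=study, sheet_name=sheet_name,
            sheet_description=sheet_desc, variable_name=name,
            variable_label=label, derivation_rule=rule,
        )

    idx = 0
    for i in range(n_matched):
        concept = concepts[idx]
        idx += 1
        src = make_record(concept, "src", i)
        src_records.append(src)
        n_true = 1
        if rng.random() < config.multi_match_rate:
            n_true = int(rng.integers(2, 4))
        for j in range(n_true):
            tgt = make_record(concept, "tgt", f"{i}_{j}" if j else i)
            tgt_records.append(tgt)
            pairs.append((src.variable_name, tgt.variable_name))

    for i in range(n_unmatched_src):
        concept = concepts[idx]
        idx += 1
        src_records.append(make_record(concept, "src", n_matched + i))

    n_distractors = config.n_target - len(tgt_records)
    if n_distractors < 0:
        raise ValidationError(
            "n_target too small for the generated true targets; "
            "increase n_target or lower multi_match_rate"
        )
    if idx + n_distractors > len(concepts):
        raise ValidationError("n_target exceeds the available concept pool")
    for i in range(n_distractors):
        concept = concepts[idx]
        idx += 1
        tgt_records.append(make_record(concept, "tgt", 1000 + i))

    source_dict = StudyDictionary("SRC", src_records)
    target_dict = StudyDictionary("TGT", tgt_records)
    truth = MatchTable.from_pairs(pairs, source_dict, target_dict)
    return source_dict, target_dict, truth


@dataclass
class LongFormatFixture:
    """A long-format questionnaire sheet plus everything needed to test the
    wide transform end-to-end."""

    rows: pd.DataFrame
    spec: LongFormatSpec
    source_records: list[VariableRecord]
    target_records: list[VariableRecord]
    pairs: list[tuple[str, str]]


def generate_long_format_sheet(
    config: SynthConfig | None = None, n_questions: int = 11
) -> LongFormatFixture:
    """Emit a long-format (question-number, score) sheet with its transform
    spec, and the wide target-side equivalents as ground truth."""
    if n_questions < 1:
        raise ValidationError("n_questions must be >= 1")
    config = config or SynthConfig()
    rng = np.random.default_rng([config.seed, 99])
    questions = list(range(1, n_questions + 1))
    rows = pd.DataFrame(
        {
            "QSTNUM": questions * 2,
            "QSTRN": rng.integers(0, 2, size=2 * n_questions),
        }
    )
    spec = LongFormatSpec(
        sheet_name="COGTEST_S",
        key_variable="QSTNUM",
        value_variable="QSTRN",
        label_template="Correct response to cognitive test question {q}",
    )
    source_records = [
        VariableRecord("SRC", "COGTEST_S", "Cognitive Test Long Format",
                       "QSTNUM", "Cognitive test question number"),
        VariableRecord("SRC", "COGTEST_S", "Cognitive Test Long Format",
                       "QSTRN", "Cognitive test item result numeric"),
    ]
    target_records = [
        VariableRecord(
            "TGT", "COGTEST_T", "Cognitive Test per visit",
            f"CT_Q{q}", f"Correct response to cognitive test question {q}",
        )
        for q in questions
    ]
    pairs = [(f"QSTRN_{q}", f"CT_Q{q}") for q in questions]
    return LongFormatFixture(rows=rows, spec=spec,
                             source_records=source_records,
                             target_records=target_records, pairs=pairs)
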