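"""Data model and I/O for study data dictionaries and ground-truth match tables.

A *data dictionary* is the metadata table a cohort study publishes alongside
its data: one row per variable, carrying the variable name, a human-readable
label, the name and description of the data sheet holding the variable, and an
optional free-text derivation rule.  Variable matching operates purely on
these dictionaries, never on participant-level values — with one exception:
questionnaire sheets stored in long format (question-number column plus score
column) are reshaped into one synthetic variable per question so that both
studies expose the same wide structure before matching.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical column names; keys are the logical fields, values the defaults
DEFAULT_COLUMNS: dict[str, str] = {
    "study_id": "study_id",
    "sheet_name": "sheet_name",
    "sheet_description": "sheet_description",
    "variable_name": "variable_name",
    "variable_label": "variable_label",
    "derivation_rule": "derivation_rule",
}


@dataclass(frozen=True)
class VariableRecord:
    """One data-dictionary entry.

    ``derivation_rule`` may be the empty string; emptiness is meaningful (it
    feeds the rule-absence feature) and is never coerced to a placeholder.
    """

    study_id: str
    sheet_name: str
    sheet_description: str
    variable_name: str
    variable_label: str
    derivation_rule: str = ""

    @property
    def rule_absent(self) -> bool:
        return self.derivation_rule == ""


@dataclass
class StudyDictionary:
    """An ordered collection of :class:`VariableRecord` for one study.

    Iteration order is file order, so candidate rankings are deterministic.
    """

    study_id: str
    records: list[VariableRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.variable_name: r for r in self.records}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            dups = sorted(
                {r.variable_name for r in self.records
                 if r.variable_name in seen or seen.add(r.variable_name)}
            )
            raise ValidationError(
                f"duplicate variable names in study {self.study_id!r}: {dups}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariableRecord]:
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> VariableRecord:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"variable {name!r} not in study {self.study_id!r}"
            ) from None

    @property
    def variable_names(self) -> list[str]:
        return [r.variable_name for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records],
                            columns=list(DEFAULT_COLUMNS))


class MatchTable:
    """Ground-truth source → target alignments; one-to-many allowed."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: list[tuple[str, str]] = list(pairs)
        index: dict[str, set[str]] = {}
        for src, tgt in self.pairs:
            index.setdefault(src, set()).add(tgt)
        self.targets_of: dict[str, set[str]] = index

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        src, tgt = pair
        return tgt in self.targets_of.get(src, ())

    @property
    def sources(self) -> list[str]:
        return list(self.targets_of)

    @property
    def n_sources(self) -> int:
        return len(self.targets_of)

    @property
    def n_multi_match(self) -> int:
        return sum(1 for t in self.targets_of.values() if len(t) > 1)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        source_dict: StudyDictionary,
        target_dict: StudyDictionary,
    ) -> "MatchTable":
        pairs = list(pairs)
        for i, (src, tgt) in enumerate(pairs):
            if src not in source_dict:
                raise ValidationError(
                    f"row {i + 1}: unknown source variable {src!r}"
                )
            if tgt not in target_dict:
                raise ValidationError(
                    f"row {i + 1}: unknown target variable {tgt!r}"
                )
        return cls(pairs)


@dataclass(frozen=True)
class LongFormatSpec:
    """Description of one long-format questionnaire sheet.

    ``key_variable`` holds the question number, ``value_variable`` the score;
    ``label_template`` must contain the placeholder ``{q}``, instantiated per
    question number when widening.
    """

    sheet_name: str
    key_variable: str
    value_variable: str
    label_template: str

    def __post_init__(self) -> None:
        if self.key_variable == self.value_variable:
            raise ValidationError(
                "key_variable and value_variable must differ"
            )
        if "{q}" not in self.label_template:
            raise ValidationError(
                "label_template must contain the {q} placeholder"
            )


def _norm(text: object) -> str:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ""
    return unicodedata.normalize("NFC", str(text)).strip()


def read_dictionary(
    path: str | Path,
    *,
    delimiter: str | None = None,
    encoding: str = "utf-8",
    column_map: Mapping[str, str] | None = None,
    study_id: str | None = None,
) -> StudyDictionary:
    """Load and validate a study data dictionary from CSV/TSV.

    ``column_map`` maps logical field names (keys of :data:`DEFAULT_COLUMNS`)
    to the actual header names in the file.  Missing derivation rules load as
    empty strings; all text is NFC-normalized and whitespace-trimmed.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=delimiter, encoding=encoding,
                        dtype=str, keep_default_na=False)

    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(frame.columns)}"
        )

    records = []
    empty_labels = []
    for _, row in frame.iterrows():
        rec = VariableRecord(
            study_id=_norm(row[cols["study_id"]]),
            sheet_name=_norm(row[cols["sheet_name"]]),
            sheet_description=_norm(row[cols["sheet_description"]]),
            variable_name=_norm(row[cols["variable_name"]]),
            variable_label=_norm(row[cols["variable_label"]]),
            derivation_rule=_norm(row[cols["derivation_rule"]]),
        )
        if not rec.variable_name:
            raise ValidationError(f"{path.name}: empty variable name")
        if not rec.variable_label:
            empty_labels.append(rec.variable_name)
        records.append(rec)
    if empty_labels:
        raise ValidationError(
            f"{path.name}: empty variable label for {sorted(empty_labels)}"
        )
    sid = study_id or (records[0].study_id if records else path.stem)
    return StudyDictionary(study_id=sid, records=records)


def write_dictionary(dictionary: StudyDictionary, path: str | Path,
                     *, delimiter: str = ",") -> None:
    dictionary.to_frame().to_csv(path, sep=delimiter, index=False)


def read_match_table(
    path: str | Path,
    source_dict: StudyDictionary,
    target_dict: StudyDictionary,
    *,
    delimiter: str = ",",
) -> MatchTable:
    """Load a 2-column (source,target) ground-truth CSV and validate every
    name against the two dictionaries."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SchemaError(
            f"{Path(path).name}: expected 2 columns (source,target)"
        )
    pairs = [(_norm(s), _norm(t)) for s, t in frame.iloc[:, :2].itertuples(index=False)]
    return MatchTable.from_pairs(pairs, source_dict, target_dict)


def long_to_wide(
    dictionary: StudyDictionary,
    data_rows: pd.DataFrame,
    spec: LongFormatSpec,
) -> StudyDictionary:
    """Replace a long-format (question-number, score) variable pair with one
    synthetic wide variable per distinct question number.

    Synthetic names are ``value_variable + "_" + key``; labels come from
    ``spec.label_template``.  All other records are untouched and keep their
    file order; the new records take the position of the value variable.
    """
    has_key = spec.key_variable in dictionary
    has_value = spec.value_variable in dictionary
    if not has_key and not has_value:
        # already widened (or never long): the transform is a no-op
        return dictionary
    if has_key != has_value:
        raise ValidationError(
            f"sheet {spec.sheet_name!r}: {spec.key_variable!r} and "
            f"{spec.value_variable!r} must both exist in the dictionary"
        )
    if len(data_rows) == 0 or spec.key_variable not in data_rows.columns:
        warnings.warn(
            f"sheet {spec.sheet_name!r}: no data rows; dictionary unchanged",
            stacklevel=2,
        )
        return dictionary

    keys = sorted({str(k) for k in data_rows[spec.key_variable] if str(k) != ""})
    if not keys:
        warnings.warn(
            f"sheet {spec.sheet_name!r}: no question keys; dictionary unchanged",
            stacklevel=2,
        )
        return dictionary

    value_rec = dictionary[spec.value_variable]
    new_records: list[VariableRecord] = []
    for key in keys:
        safe_key = key
        if "_" in key:
            safe_key = key.replace("_", "-")
            warnings.warn(
                f"question key {key!r} contains the name separator; "
                f"sanitized to {safe_key!r}",
                stacklevel=2,
            )
        new_records.append(
            replace(
                value_rec,
                variable_name=f"{spec.value_variable}_{safe_key}",
                variable_label=spec.label_template.format(q=key),
            )
        )

    out: list[VariableRecord] = []
    for rec in dictionary:
        if rec.variable_name == spec.key_variable:
            continue
        if rec.variable_name == spec.value_variable:
            out.extend(new_records)
        else:
            out.append(rec)
    return StudyDictionary(study_id=dictionary.study_id, records=out)
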