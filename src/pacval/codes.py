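"""ICD-10 malignancy code classification and clinical cancer groupings.

Hospital discharge diagnoses are coded in ICD-10(-AM).  Malignant neoplasms
occupy the range C00–C96; within it, C77–C79 denote secondary (metastatic)
sites and must be excluded when the aim is *incident primary* cancers.
In-situ and benign neoplasms carry D-prefixed codes and fall outside the
range altogether, so a plain range filter realises the in-situ/benign
exclusion.  Primary cancers are analysed in 13 clinical groups (melanoma,
breast, thyroid and other endocrine, ...).  The default stem-range mapping
follows the ICD-10 chapter blocks and ships with the package; it can be
overridden from a YAML file for registries that draw the group boundaries
differently.

Codes are compared on their three-character alphanumeric stem; dot-suffix
subdivisions ("C50.9" -> "C50") never change the group.  Stems that ICD-10
leaves unassigned (C27–C29, C35–C36, C42, C59) and non-melanoma skin cancer
(C44, not notifiable to the registry) classify as out of scope.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ClinicalGroup",
    "Classification",
    "CodeMap",
    "CodeParseError",
    "classify_code",
    "record_group",
    "MAX_DIAGNOSIS_FIELDS",
]

MAX_DIAGNOSIS_FIELDS = 22


class ClinicalGroup(str, enum.Enum):
    """The 13 clinical groupings used for primary cancers."""

    MELANOMA = "melanoma"
    BREAST = "breast"
    THYROID_ENDOCRINE = "thyroid_endocrine"
    GYNAECOLOGICAL = "gynaecological"
    LYMPHOHAEMATOPOEITIC = "lymphohaematopoeitic"
    COLORECTAL = "colorectal"
    NEUROLOGICAL = "neurological"
    BONE_CONNECTIVE = "bone_connective"
    HEAD_NECK = "head_neck"
    UPPER_GI = "upper_gi"
    RESPIRATORY = "respiratory"
    ILL_DEFINED_UNKNOWN = "ill_defined_unknown"
    UROGENITAL = "urogenital"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Table-row order used throughout reporting (most to least frequent in the
#: registry, "any" appended by the reporting layer).
GROUP_ORDER: tuple[ClinicalGroup, ...] = (
    ClinicalGroup.MELANOMA,
    ClinicalGroup.BREAST,
    ClinicalGroup.THYROID_ENDOCRINE,
    ClinicalGroup.GYNAECOLOGICAL,
    ClinicalGroup.LYMPHOHAEMATOPOEITIC,
    ClinicalGroup.COLORECTAL,
    ClinicalGroup.NEUROLOGICAL,
    ClinicalGroup.BONE_CONNECTIVE,
    ClinicalGroup.HEAD_NECK,
    ClinicalGroup.UPPER_GI,
    ClinicalGroup.RESPIRATORY,
    ClinicalGroup.ILL_DEFINED_UNKNOWN,
    ClinicalGroup.UROGENITAL,
)


class CodeParseError(ValueError):
    """Raised for a diagnosis code without a leading letter + two digits."""

    def __init__(self, code: object):
        super().__init__(f"malformed diagnosis code: {code!r}")
        self.code = code


_STEM_RE = re.compile(r"^([A-Z])([0-9]{2})")


def code_stem(code: str) -> str:
    """Normalise a diagnosis code to its 3-character stem (e.g. 'C50').

    Input is stripped and upper-cased; anything after the stem (dot
    subdivisions, trailing characters) is ignored for classification.
    """
    if not isinstance(code, str):
        raise CodeParseError(code)
    normalised = code.strip().upper()
    m = _STEM_RE.match(normalised)
    if m is None:
        raise CodeParseError(code)
    return m.group(0)


def _stem_key(stem: str) -> tuple[str, int]:
    return stem[0], int(stem[1:3])


def _stems_in_range(lo: str, hi: str) -> list[str]:
    letter_lo, num_lo = _stem_key(lo)
    letter_hi, num_hi = _stem_key(hi)
    if letter_lo != letter_hi or num_lo > num_hi:
        raise ValueError(f"invalid stem range {lo}–{hi}")
    return [f"{letter_lo}{n:02d}" for n in range(num_lo, num_hi + 1)]


INCIDENT_CANDIDATE = "incident_candidate"
SECONDARY = "secondary"
OUT_OF_SCOPE = "out_of_scope"


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one diagnosis code."""

    kind: str
    group: ClinicalGroup | None = None

    @property
    def is_incident_candidate(self) -> bool:
        return self.kind == INCIDENT_CANDIDATE

    @property
    def is_secondary(self) -> bool:
        return self.kind == SECONDARY


_DEFAULT_GROUP_RANGES: tuple[tuple[str, str, ClinicalGroup], ...] = (
    ("C00", "C14", ClinicalGroup.HEAD_NECK),
    ("C15", "C17", ClinicalGroup.UPPER_GI),
    ("C18", "C21", ClinicalGroup.COLORECTAL),
    ("C22", "C26", ClinicalGroup.UPPER_GI),
    ("C30", "C32", ClinicalGroup.HEAD_NECK),
    ("C33", "C34", ClinicalGroup.RESPIRATORY),
    ("C37", "C39", ClinicalGroup.RESPIRATORY),
    ("C40", "C41", ClinicalGroup.BONE_CONNECTIVE),
    ("C43", "C43", ClinicalGroup.MELANOMA),
    ("C45", "C49", ClinicalGroup.BONE_CONNECTIVE),
    ("C50", "C50", ClinicalGroup.BREAST),
    ("C51", "C58", ClinicalGroup.GYNAECOLOGICAL),
    ("C60", "C68", ClinicalGroup.UROGENITAL),
    ("C69", "C72", ClinicalGroup.NEUROLOGICAL),
    ("C73", "C75", ClinicalGroup.THYROID_ENDOCRINE),
    ("C76", "C76", ClinicalGroup.ILL_DEFINED_UNKNOWN),
    ("C80", "C80", ClinicalGroup.ILL_DEFINED_UNKNOWN),
    ("C81", "C96", ClinicalGroup.LYMPHOHAEMATOPOEITIC),
)

_DEFAULT_SECONDARY_RANGES: tuple[tuple[str, str], ...] = (("C77", "C79"),)

#: Stems in C00–C96 that classify out of scope on purpose: ICD-10 gaps plus
#: non-melanoma skin cancer (C44), which the registry does not collect.
DEFAULT_SCOPE_GAPS: frozenset[str] = frozenset(
    {"C27", "C28", "C29", "C35", "C36", "C42", "C44", "C59"}
)


@dataclass
class CodeMap:
    """Mapping from code stems to clinical groups plus exclusion rules.

    ``group_ranges`` are inclusive stem ranges assigned to a group;
    ``secondary_ranges`` mark secondary/metastatic stems; everything in
    ``eligible_range`` not covered by either classifies out of scope.
    """

    group_ranges: Sequence[tuple[str, str, ClinicalGroup]] = _DEFAULT_GROUP_RANGES
    secondary_ranges: Sequence[tuple[str, str]] = _DEFAULT_SECONDARY_RANGES
    eligible_range: tuple[str, str] = ("C00", "C96")
    _lookup: dict[str, Classification] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )
    _eligible: frozenset[str] = field(
        init=False, repr=False, compare=False, default=frozenset()
    )

    def __post_init__(self) -> None:
        lookup: dict[str, Classification] = {}
        for lo, hi, group in self.group_ranges:
            group = ClinicalGroup(group)
            for stem in _stems_in_range(lo, hi):
                if stem in lookup:
                    raise ValueError(f"overlapping code ranges at stem {stem}")
                lookup[stem] = Classification(INCIDENT_CANDIDATE, group)
        eligible = set(_stems_in_range(*self.eligible_range))
        for lo, hi in self.secondary_ranges:
            for stem in _stems_in_range(lo, hi):
                if stem in lookup:
                    raise ValueError(f"overlapping code ranges at stem {stem}")
                if stem not in eligible:
                    raise ValueError(f"secondary stem {stem} outside eligible range")
                lookup[stem] = Classification(SECONDARY)
        if not set(lookup) <= eligible:
            extra = sorted(set(lookup) - eligible)
            raise ValueError(f"group ranges outside eligible range: {extra}")
        self._lookup = lookup
        self._eligible = frozenset(eligible)

    # -- classification ---------------------------------------------------

    def classify(self, code: str) -> Classification:
        stem = code_stem(code)
        if stem not in self._eligible:
            return Classification(OUT_OF_SCOPE)
        return self._lookup.get(stem, Classification(OUT_OF_SCOPE))

    def stem_lookup(self) -> dict[str, Classification]:
        """Full stem → classification table for the eligible range."""
        out = {}
        for stem in _stems_in_range(*self.eligible_range):
            out[stem] = self._lookup.get(stem, Classification(OUT_OF_SCOPE))
        return out

    def groups(self) -> tuple[ClinicalGroup, ...]:
        return GROUP_ORDER

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "eligible_range": {
                "start": self.eligible_range[0],
                "end": self.eligible_range[1],
            },
            "group_ranges": [
                {"prefix_start": lo, "prefix_end": hi, "group": ClinicalGroup(g).value}
                for lo, hi, g in self.group_ranges
            ],
            "secondary_ranges": [
                {"prefix_start": lo, "prefix_end": hi}
                for lo, hi in self.secondary_ranges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeMap":
        return cls(
            group_ranges=[
                (r["prefix_start"], r["prefix_end"], ClinicalGroup(r["group"]))
                for r in d["group_ranges"]
            ],
            secondary_ranges=[
                (r["prefix_start"], r["prefix_end"]) for r in d["secondary_ranges"]
            ],
            eligible_range=(
                d["eligible_range"]["start"],
                d["eligible_range"]["end"],
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeMap":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "CodeMap":
        return cls()


def classify_code(code: str, codemap: CodeMap | None = None) -> Classification:
    """Classify one diagnosis code as incident candidate / secondary / out of scope."""
    return (codemap or CodeMap.default()).classify(code)


def record_group(
    codes: Iterable[str], codemap: CodeMap | None = None
) -> ClinicalGroup | None:
    """Assign one clinical group to a multi-coded record.

    Scans the diagnosis fields in listed order and returns the group of the
    first incident-candidate code; secondary and out-of-scope codes are
    skipped.  Returns None when no code qualifies.
    """
    codemap = codemap or CodeMap.default()
    code_list = list(codes)
    if not code_list:
        raise ValueError("record has no diagnosis codes")
    if len(code_list) > MAX_DIAGNOSIS_FIELDS:
        raise ValueError(
            f"record has {len(code_list)} diagnosis codes; at most "
            f"{MAX_DIAGNOSIS_FIELDS} fields are searched"
        )
    for code in code_list:
        c = codemap.classify(code)
        if c.is_incident_candidate:
            return c.group
    return None
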