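"""ICD-10 code parsing and cause-of-death classification.

Suicide is defined as an underlying cause in X60-X84 or Y87.0 (sequelae of
intentional self-harm).  Suicides are further split into four mechanism
groups used throughout the package:

* ``hanging``    — X70
* ``firearm``    — X72-X74
* ``poisoning``  — X60-X69
* ``other_method`` — X71, X75-X83, plus X84 (unspecified means) and Y87.0
  (sequelae), neither of which carries mechanism information.

Codes that are uninformative for cause-of-death analysis ("garbage codes",
e.g. undetermined-intent deaths Y10-Y34) are recognised through a
:class:`GCMap`, which also names the target cause groups each garbage-code
group should be redistributed to and whether the redistribution is driven
by empirical weights or by the observed proportional mix of targets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import yaml

__all__ = [
    "ICDCode",
    "CauseCategory",
    "GCMap",
    "GCRange",
    "parse_icd10",
    "classify_cause",
    "classify_method",
    "SUICIDE_METHODS",
]

SUICIDE_METHODS = ("hanging", "firearm", "poisoning", "other_method")

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.?(\d))?$")


@dataclass(frozen=True, order=True)
class ICDCode:
    """A canonical ICD-10 code: letter, two-digit major, optional subcategory."""

    letter: str
    major: int
    sub: Optional[int] = None

    def __post_init__(self) -> None:
        if not ("A" <= self.letter <= "Z"):
            raise ValueError(f"ICD letter must be A-Z, got {self.letter!r}")
        if not (0 <= self.major <= 99):
            raise ValueError(f"ICD major must be 0-99, got {self.major!r}")
        if self.sub is not None and not (0 <= self.sub <= 9):
            raise ValueError(f"ICD subcategory must be 0-9, got {self.sub!r}")

    def __str__(self) -> str:
        base = f"{self.letter}{self.major:02d}"
        return base if self.sub is None else f"{base}.{self.sub}"

    @property
    def stem(self) -> "ICDCode":
        """The three-character code, dropping any subcategory."""
        return ICDCode(self.letter, self.major) if self.sub is not None else self


def parse_icd10(raw: str) -> ICDCode:
    """Parse an ICD-10 code in any common dialect into canonical form.

    Accepts 3- or 4-character codes, with or without the dot, in either
    case: ``"X70"``, ``"x70"``, ``"Y870"`` and ``"Y87.0"`` all parse.

    Raises
    ------
    ValueError
        If the text is empty or not a well-formed ICD-10 code; the message
        names the offending value.
    """
    if raw is None:
        raise ValueError("ICD-10 code is missing (None)")
    text = str(raw).strip().upper()
    if not text:
        raise ValueError("ICD-10 code is empty")
    m = _ICD_RE.match(text)
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {raw!r}")
    letter, major, sub = m.group(1), int(m.group(2)), m.group(3)
    return ICDCode(letter, major, None if sub is None else int(sub))


def _is_suicide(code: ICDCode) -> bool:
    if code.letter == "X" and 60 <= code.major <= 84:
        return True
    return code.letter == "Y" and code.major == 87 and code.sub == 0


def classify_method(code: ICDCode) -> str:
    """Mechanism group of a suicide code.

    Four-character subcodes inherit the three-character classification
    (X70.9 is hanging).  X84 (unspecified means) and Y87.0 (sequelae) carry
    no mechanism and fall in ``other_method``.
    """
    if not _is_suicide(code):
        raise ValueError(f"{code} is not a suicide code (X60-X84 / Y87.0)")
    if code.letter == "Y":
        return "other_method"
    if code.major == 70:
        return "hanging"
    if 72 <= code.major <= 74:
        return "firearm"
    if 60 <= code.major <= 69:
        return "poisoning"
    return "other_method"  # X71, X75-X83, X84


@dataclass(frozen=True)
class CauseCategory:
    """Classification of one underlying cause.

    ``kind`` is one of ``suicide``/``garbage``/``other``.  ``method`` is set
    iff suicide; ``gc_group`` iff garbage.  ``target_group`` names the
    defined cause group a non-suicide, non-garbage code belongs to when the
    GC map defines one (used as redistribution target), else None.
    """

    kind: Literal["suicide", "garbage", "other"]
    method: Optional[str] = None
    gc_group: Optional[str] = None
    target_group: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.kind == "suicide") != (self.method is not None):
            raise ValueError("method must be present iff kind='suicide'")
        if (self.kind == "garbage") != (self.gc_group is not None):
            raise ValueError("gc_group must be present iff kind='garbage'")


@dataclass(frozen=True)
class GCRange:
    start: ICDCode
    end: ICDCode
    group: str

    def __contains__(self, code: ICDCode) -> bool:
        key = (code.letter, code.major)
        return (self.start.letter, self.start.major) <= key <= (self.end.letter, self.end.major)


@dataclass
class GCMap:
    """Garbage-code map: code ranges, redistribution targets and modes.

    ``entries`` assign three-character code ranges to garbage-code groups
    (ranges must not overlap).  ``targets`` lists, per group, the ordered
    target cause groups its deaths are redistributed to, and ``modes`` says
    whether that redistribution uses empirical weights or the observed
    proportional mix.  ``target_defs`` give code ranges for the non-suicide
    target groups so proportional redistribution can observe them; the
    suicide group needs no definition here.
    """

    entries: list[GCRange] = field(default_factory=list)
    targets: dict[str, list[str]] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)
    target_defs: list[GCRange] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.targets:
            if g not in {e.group for e in self.entries}:
                raise ValueError(f"gc_group {g!r} has targets but no code range")
        for g, mode in self.modes.items():
            if mode not in ("empirical", "proportional"):
                raise ValueError(f"mode for {g!r} must be empirical|proportional, got {mode!r}")
        keys = []
        for e in self.entries:
            keys.append(((e.start.letter, e.start.major), (e.end.letter, e.end.major)))
        keys.sort()
        for (s1, e1), (s2, _) in zip(keys, keys[1:]):
            if s2 <= e1:
                raise ValueError("garbage-code ranges overlap")

    def gc_group(self, code: ICDCode) -> Optional[str]:
        for r in self.entries:
            if code in r:
                return r.group
        return None

    def target_group(self, code: ICDCode) -> Optional[str]:
        for r in self.target_defs:
            if code in r:
                return r.group
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GCMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = [
            GCRange(parse_icd10(e["code_start"]), parse_icd10(e["code_end"]), e["gc_group"])
            for e in doc.get("garbage_codes", [])
        ]
        targets = {g: list(spec["targets"]) for g, spec in doc.get("groups", {}).items()}
        modes = {g: spec["mode"] for g, spec in doc.get("groups", {}).items()}
        target_defs = [
            GCRange(parse_icd10(e["code_start"]), parse_icd10(e["code_end"]), e["target_group"])
            for e in doc.get("target_definitions", [])
        ]
        return cls(entries=entries, targets=targets, modes=modes, target_defs=target_defs)


def classify_cause(code: ICDCode, gc_map: GCMap) -> CauseCategory:
    """Classify a cause code as suicide (with method), garbage, or other.

    Total over valid codes: every code falls in exactly one kind.
    """
    if _is_suicide(code):
        return CauseCategory("suicide", method=classify_method(code))
    g = gc_map.gc_group(code)
    if g is not None:
        return CauseCategory("garbage", gc_group=g)
    return CauseCategory("other", target_group=gc_map.target_group(code))
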