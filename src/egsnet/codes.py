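"""Code-set handling: EGS diagnosis categories, complications, operations, comorbidities.

The analysis never hard-codes clinical code lists. Emergency-general-surgery (EGS)
diagnosis categories, complication diagnoses, operation/procedure codes and the
comorbidity grouper all arrive as JSON configuration. The package ships small
synthetic fixtures (``egsnet/data``) so the pipeline runs out of the box; real
analyses substitute the licensed AAST / Surgery-Flags / Elixhauser lists.

Codes are normalised to uppercase with whitespace and periods stripped, so
``"k35.2"`` and ``"K352"`` compare equal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CodeSet",
    "ComorbidityMap",
    "normalize_code",
    "load_codeset",
    "load_comorbidity_map",
    "default_codeset",
    "default_comorbidity_map",
]


def normalize_code(code: str) -> str:
    """Uppercase a clinical code and strip whitespace and periods."""
    return "".join(str(code).split()).replace(".", "").upper()


def _normset(codes: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_code(c) for c in codes)


@dataclass(frozen=True)
class CodeSet:
    """Diagnosis and procedure code lists driving cohort definitions.

    Attributes
    ----------
    egs_dx_categories : mapping of category name -> codes
        EGS condition diagnoses grouped into categories (used both for the
        EGS-episode definition and as adjustment indicators in risk models).
    complication_dx : frozenset of codes
        Diagnoses counting as in-hospital complications (failure-to-rescue).
    operation_proc : frozenset of codes
        Procedure codes counting as operations/procedures.
    """

    egs_dx_categories: Mapping[str, frozenset[str]]
    complication_dx: frozenset[str] = field(default_factory=frozenset)
    operation_proc: frozenset[str] = field(default_factory=frozenset)

    @property
    def egs_dx(self) -> frozenset[str]:
        """Union of all EGS diagnosis codes across categories."""
        out: set[str] = set()
        for codes in self.egs_dx_categories.values():
            out.update(codes)
        return frozenset(out)

    def egs_category_of(self, dx_codes: Iterable[str]) -> str | None:
        """First EGS category (alphabetically) matched by any of ``dx_codes``."""
        dx = {normalize_code(c) for c in dx_codes}
        for cat in sorted(self.egs_dx_categories):
            if dx & self.egs_dx_categories[cat]:
                return cat
        return None

    @classmethod
    def from_dict(cls, obj: Mapping) -> "CodeSet":
        egs = obj.get("egs_dx", {})
        if isinstance(egs, Mapping):
            cats = {str(k): _normset(v) for k, v in egs.items()}
        else:  # flat list -> single category
            cats = {"egs": _normset(egs)}
        return cls(
            egs_dx_categories=cats,
            complication_dx=_normset(obj.get("complication_dx", [])),
            operation_proc=_normset(obj.get("operation_proc", [])),
        )


@dataclass(frozen=True)
class ComorbidityMap:
    """Comorbidity grouper: category weights plus a code -> category map."""

    weights: Mapping[str, int]
    category_map: Mapping[str, str]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.weights))

    @classmethod
    def from_dict(cls, obj: Mapping) -> "ComorbidityMap":
        weights: dict[str, int] = {}
        cmap: dict[str, str] = {}
        for cat, entry in obj["categories"].items():
            weights[cat] = int(entry["weight"])
            for code in entry.get("codes", []):
                cmap[normalize_code(code)] = cat
        return cls(weights=weights, category_map=cmap)


def load_codeset(path: str | Path) -> CodeSet:
    with open(path) as fh:
        return CodeSet.from_dict(json.load(fh))


def load_comorbidity_map(path: str | Path) -> ComorbidityMap:
    with open(path) as fh:
        return ComorbidityMap.from_dict(json.load(fh))


def default_codeset() -> CodeSet:
    """The synthetic fixture code set shipped with the package."""
    text = resources.files("egsnet.data").joinpath("egs_codes.json").read_text()
    return CodeSet.from_dict(json.loads(text))


def default_comorbidity_map() -> ComorbidityMap:
    """The synthetic fixture comorbidity grouper shipped with the package."""
    text = resources.files("egsnet.data").joinpath("comorbidity_weights.json").read_text()
    return ComorbidityMap.from_dict(json.loads(text))
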