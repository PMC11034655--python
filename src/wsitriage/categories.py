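"""Diagnostic categories and subcategories for cervical biopsy triage.

Slides (and patches) carry one of four main diagnostic categories with a
total severity order ``normal < low_grade < high_grade < malignant``.
Subcategories refine the diagnosis (e.g. CIN 2 and CIN 3 are both high
grade; CGIN is grouped with malignant because it is treated aggressively).
"""

from __future__ import annotations

import enum
import re


class Category(enum.Enum):
    """Main diagnostic category, totally ordered by severity."""

    NORMAL = "normal"
    LOW_GRADE = "low_grade"
    HIGH_GRADE = "high_grade"
    MALIGNANT = "malignant"

    @property
    def severity_rank(self) -> int:
        return _SEVERITY[self]

    def __lt__(self, other: "Category") -> bool:
        if not isinstance(other, Category):
            return NotImplemented
        return self.severity_rank < other.severity_rank

    def __le__(self, other: "Category") -> bool:
        if not isinstance(other, Category):
            return NotImplemented
        return self.severity_rank <= other.severity_rank

    def __gt__(self, other: "Category") -> bool:
        if not isinstance(other, Category):
            return NotImplemented
        return self.severity_rank > other.severity_rank

    def __ge__(self, other: "Category") -> bool:
        if not isinstance(other, Category):
            return NotImplemented
        return self.severity_rank >= other.severity_rank

    @classmethod
    def parse(cls, text: str) -> "Category":
        """Parse a category from free-form text (e.g. ``"High Grade"``)."""
        key = _normalize(text)
        try:
            return _CATEGORY_ALIASES[key]
        except KeyError:
            raise ValueError(f"unknown category: {text!r}") from None


_SEVERITY = {
    Category.NORMAL: 0,
    Category.LOW_GRADE: 1,
    Category.HIGH_GRADE: 2,
    Category.MALIGNANT: 3,
}

#: Categories in increasing severity; index == severity_rank.
CATEGORIES: tuple[Category, ...] = (
    Category.NORMAL,
    Category.LOW_GRADE,
    Category.HIGH_GRADE,
    Category.MALIGNANT,
)


class SubCategory(enum.Enum):
    SQUAMOUS_CARCINOMA = "squamous_carcinoma"
    ADENOCARCINOMA = "adenocarcinoma"
    CGIN = "cgin"
    OTHER = "other"
    CIN2 = "cin2"
    CIN3 = "cin3"
    CIN1 = "cin1"
    HPV = "hpv"
    NORMAL_INFLAMMATION = "normal_inflammation"

    @property
    def parent(self) -> Category:
        return _PARENT[self]

    @classmethod
    def parse(cls, text: str) -> "SubCategory":
        """Parse a subcategory from free-form text (e.g. ``"CIN 2"``)."""
        key = _normalize(text)
        try:
            return _SUBCATEGORY_ALIASES[key]
        except KeyError:
            raise ValueError(f"unknown subcategory: {text!r}") from None


_PARENT = {
    SubCategory.SQUAMOUS_CARCINOMA: Category.MALIGNANT,
    SubCategory.ADENOCARCINOMA: Category.MALIGNANT,
    SubCategory.CGIN: Category.MALIGNANT,
    SubCategory.OTHER: Category.MALIGNANT,
    SubCategory.CIN2: Category.HIGH_GRADE,
    SubCategory.CIN3: Category.HIGH_GRADE,
    SubCategory.CIN1: Category.LOW_GRADE,
    SubCategory.HPV: Category.LOW_GRADE,
    SubCategory.NORMAL_INFLAMMATION: Category.NORMAL,
}

#: Default subcategory to use when only the main category is known.
DEFAULT_SUBCATEGORY = {
    Category.NORMAL: SubCategory.NORMAL_INFLAMMATION,
    Category.LOW_GRADE: SubCategory.HPV,
    Category.HIGH_GRADE: SubCategory.CIN2,
    Category.MALIGNANT: SubCategory.SQUAMOUS_CARCINOMA,
}


def _normalize(text: str) -> str:
    # "CIN 2" -> "cin2"; "Normal/inflammation" -> "normal_inflammation"
    key = re.sub(r"[\s\-]+", "_", text.strip().lower())
    key = key.replace("/", "_")
    key = re.sub(r"_+", "_", key)
    key = re.sub(r"cin_(\d)", r"cin\1", key)
    return key


_CATEGORY_ALIASES = {
    "normal": Category.NORMAL,
    "normal_inflammation": Category.NORMAL,
    "low_grade": Category.LOW_GRADE,
    "high_grade": Category.HIGH_GRADE,
    "malignant": Category.MALIGNANT,
}

_SUBCATEGORY_ALIASES = {
    "squamous_carcinoma": SubCategory.SQUAMOUS_CARCINOMA,
    "adenocarcinoma": SubCategory.ADENOCARCINOMA,
    "adeno_carcinoma": SubCategory.ADENOCARCINOMA,
    "cgin": SubCategory.CGIN,
    "other": SubCategory.OTHER,
    "cin2": SubCategory.CIN2,
    "cin3": SubCategory.CIN3,
    "cin1": SubCategory.CIN1,
    "hpv": SubCategory.HPV,
    "normal_inflammation": SubCategory.NORMAL_INFLAMMATION,
    "normal": SubCategory.NORMAL_INFLAMMATION,
}
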