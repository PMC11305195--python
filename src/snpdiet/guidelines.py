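"""Beneficiary categories and nutrient guideline sets.

Macronutrient targets follow the Government-of-India supplementary-nutrition
rules per beneficiary category (kcal / g protein / g fat per day).  Packaged
micronutrient guideline values exist for the two worked-example child
categories; other categories carry macros only until the user supplies
micronutrient values.  Several micronutrient guideline values represent
one-third of the estimated average requirement (a single-meal share); these
are flagged per nutrient.

Targets of 0 mean "no lower bound", not "force zero intake".  Tolerable upper
limits ship empty and are user-supplied.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .nutrients import MACROS, NUTRIENT_FIELDS, NutrientVector


class GuidelineError(ValueError):
    pass


class BeneficiaryCategory(enum.Enum):
    CHILD_6_12M = "child_6_12m"
    CHILD_1_3Y = "child_1_3y"
    CHILD_3_6Y = "child_3_6y"
    SAM_CHILD_6_12M = "sam_child_6_12m"
    SAM_CHILD_1_3Y = "sam_child_1_3y"
    SAM_CHILD_3_6Y = "sam_child_3_6y"
    PREGNANT_WOMAN = "pregnant_woman"
    LACTATING_WOMAN = "lactating_woman"

    @classmethod
    def parse(cls, label: str) -> "BeneficiaryCategory":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise GuidelineError(
                f"unknown beneficiary category {label!r}; valid: {valid}"
            ) from None


# Macro guideline matrix: category -> (energy kcal, protein g, fat g) per day.
_MACRO_MATRIX: dict[BeneficiaryCategory, tuple[float, float, float]] = {
    BeneficiaryCategory.CHILD_6_12M: (200.0, 8.0, 10.0),
    BeneficiaryCategory.CHILD_1_3Y: (400.0, 15.0, 15.0),
    BeneficiaryCategory.CHILD_3_6Y: (400.0, 15.0, 15.0),
    BeneficiaryCategory.SAM_CHILD_6_12M: (400.0, 15.0, 15.0),
    BeneficiaryCategory.SAM_CHILD_1_3Y: (700.0, 25.0, 25.0),
    BeneficiaryCategory.SAM_CHILD_3_6Y: (800.0, 25.0, 25.0),
    BeneficiaryCategory.PREGNANT_WOMAN: (600.0, 22.0, 22.0),
    BeneficiaryCategory.LACTATING_WOMAN: (600.0, 22.0, 22.0),
}

# Packaged micronutrient guideline values (per day, single-meal share) for the
# two child categories with published worked examples.  Flagged nutrients
# represent one-third of the estimated average requirement.
_MICROS_3_6Y: dict[str, float] = {
    "calcium_mg": 150.0,
    "fiber_g": 6.8,
    "folate_ug": 40.0,
    "iron_mg": 3.0,
    "magnesium_mg": 34.7,
    "vitamin_b3_mg": 2.7,
    "vitamin_b6_mg": 0.3,
    "vitamin_b2_mg": 0.4,
    "vitamin_b1_mg": 0.3,
    "vitamin_a_ug": 80.0,
    "vitamin_b12_ug": 0.7,
    "vitamin_c_mg": 9.0,
    "zinc_mg": 1.5,
}
_THIRD_EAR_3_6Y = {
    "fiber_g", "magnesium_mg", "vitamin_b3_mg", "vitamin_b2_mg",
    "vitamin_b1_mg", "vitamin_c_mg",
}

_MICROS_1_3Y: dict[str, float] = {
    "calcium_mg": 135.0,
    "fiber_g": 5.6,
    "folate_ug": 35.0,
    "iron_mg": 2.0,
    "magnesium_mg": 24.3,
    "vitamin_a_ug": 60.0,
    "vitamin_b1_mg": 0.2,
    "vitamin_b12_ug": 0.3,
    "vitamin_b2_mg": 0.3,
    "vitamin_b3_mg": 2.0,
    "vitamin_b6_mg": 0.3,
    "vitamin_c_mg": 8.0,
    "zinc_mg": 1.0,
}
_THIRD_EAR_1_3Y = {
    "fiber_g", "magnesium_mg", "vitamin_b1_mg", "vitamin_b2_mg",
    "vitamin_b3_mg", "vitamin_c_mg",
}

#: Default macro bands (low, high) as fractions of the target.  Energy is held
#: essentially at target; protein and fat may run 90%–135% of target, which is
#: the slack real optimized program menus exhibit.
DEFAULT_MACRO_BAND: dict[str, tuple[float, float]] = {
    "energy_kcal": (1.00, 1.02),
    "protein_g": (0.90, 1.35),
    "fat_g": (0.90, 1.35),
}


@dataclass(frozen=True)
class GuidelineSet:
    """Per-category nutrient targets, optional upper limits, and macro bands."""

    category: BeneficiaryCategory
    targets: NutrientVector
    one_third_ear_flags: frozenset[str] = frozenset()
    upper_limits: NutrientVector | None = None
    macro_band: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MACRO_BAND)
    )

    def __post_init__(self):
        for macro in MACROS:
            lo, hi = self.macro_band.get(macro, (1.0, 1.0))
            if not (lo <= 1.0 <= hi):
                raise GuidelineError(
                    f"macro_band for {macro}: need low <= 1 <= high, got ({lo}, {hi})"
                )
        if self.upper_limits is not None:
            for name in NUTRIENT_FIELDS:
                ul = self.upper_limits[name]
                if ul > 0 and ul < self.targets[name]:
                    raise GuidelineError(
                        f"upper_limit({name})={ul} is below target {self.targets[name]}"
                    )
        unknown = set(self.one_third_ear_flags) - set(NUTRIENT_FIELDS)
        if unknown:
            raise GuidelineError(f"unknown nutrient(s) in flags: {sorted(unknown)}")

    def macro_bounds(self, macro: str) -> tuple[float, float]:
        """Absolute (low, high) bounds for a macronutrient from target x band."""
        lo, hi = self.macro_band[macro]
        t = self.targets[macro]
        return lo * t, hi * t

    def with_target(self, nutrient: str, value: float) -> "GuidelineSet":
        d = self.targets.as_dict()
        d[nutrient] = value
        return replace(self, targets=NutrientVector(d))


def default_guidelines(category: BeneficiaryCategory | str) -> GuidelineSet:
    """Packaged default guideline set for a beneficiary category.

    Pure and total over the enumeration: macros for every category;
    micronutrient values additionally for the 1-3 y and 3-6 y child
    categories.
    """
    if isinstance(category, str):
        category = BeneficiaryCategory.parse(category)
    energy, protein, fat = _MACRO_MATRIX[category]
    values = {"energy_kcal": energy, "protein_g": protein, "fat_g": fat}
    flags: set[str] = set()
    if category is BeneficiaryCategory.CHILD_3_6Y:
        values.update(_MICROS_3_6Y)
        flags = set(_THIRD_EAR_3_6Y)
    elif category is BeneficiaryCategory.CHILD_1_3Y:
        values.update(_MICROS_1_3Y)
        flags = set(_THIRD_EAR_1_3Y)
    return GuidelineSet(
        category=category,
        targets=NutrientVector(values),
        one_third_ear_flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# I/O

def save_guidelines(gs: GuidelineSet, path: str | Path) -> None:
    doc = {
        "category": gs.category.value,
        "targets": gs.targets.as_dict(),
        "one_third_ear_flags": sorted(gs.one_third_ear_flags),
        "upper_limits": gs.upper_limits.as_dict() if gs.upper_limits else None,
        "macro_band": {k: list(v) for k, v in gs.macro_band.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_guidelines(path: str | Path) -> GuidelineSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    band = {k: (float(v[0]), float(v[1])) for k, v in doc.get("macro_band", {}).items()}
    for macro, (lo, hi) in band.items():
        if lo > hi:
            raise GuidelineError(f"macro_band for {macro} inverted: low {lo} > high {hi}")
    ul = doc.get("upper_limits")
    return GuidelineSet(
        category=BeneficiaryCategory.parse(doc["category"]),
        targets=NutrientVector(doc["targets"]),
        one_third_ear_flags=frozenset(doc.get("one_third_ear_flags", ())),
        upper_limits=NutrientVector(ul) if ul else None,
        macro_band=band or dict(DEFAULT_MACRO_BAND),
    )
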