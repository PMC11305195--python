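"""Fixed-schema nutrient vectors.

Sixteen nutrients are tracked throughout the package, in the fixed order and
units below (amounts per 100 g for foods, per serving for recipes, per day for
solutions).  The vector is a thin immutable wrapper around a numpy array so
that componentwise addition and scalar scaling are exact up to floating-point
accumulation.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

#: Canonical nutrient field names, with units embedded (also the food-CSV headers).
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "fiber_g",
    "calcium_mg",
    "zinc_mg",
    "iron_mg",
    "magnesium_mg",
    "vitamin_a_ug",
    "folate_ug",
    "vitamin_b12_ug",
    "vitamin_b1_mg",
    "vitamin_b2_mg",
    "vitamin_b3_mg",
    "vitamin_b6_mg",
    "vitamin_c_mg",
)

N_NUTRIENTS = len(NUTRIENT_FIELDS)
_INDEX = {name: i for i, name in enumerate(NUTRIENT_FIELDS)}

#: The three macronutrients subject to guideline bands.
MACROS: tuple[str, ...] = ("energy_kcal", "protein_g", "fat_g")


class NutrientVector:
    """Immutable vector of the 16 tracked nutrient amounts.

    All components must be finite and >= 0.  Supports ``+`` (componentwise)
    and ``*`` by a nonnegative scalar; both return new vectors.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Iterable[float] | Mapping[str, float] | None = None):
        if values is None:
            arr = np.zeros(N_NUTRIENTS)
        elif isinstance(values, Mapping):
            arr = np.zeros(N_NUTRIENTS)
            for name, v in values.items():
                if name not in _INDEX:
                    raise KeyError(f"unknown nutrient {name!r}")
                arr[_INDEX[name]] = float(v)
        else:
            arr = np.asarray(list(values), dtype=float)
            if arr.shape != (N_NUTRIENTS,):
                raise ValueError(
                    f"expected {N_NUTRIENTS} nutrient values, got {arr.shape}"
                )
        if not np.all(np.isfinite(arr)):
            raise ValueError("nutrient values must be finite")
        if np.any(arr < 0):
            bad = NUTRIENT_FIELDS[int(np.argmax(arr < 0))]
            raise ValueError(f"nutrient {bad!r} is negative")
        arr.flags.writeable = False
        self._values = arr

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """Read-only numpy view in canonical field order."""
        return self._values

    def __getitem__(self, name: str) -> float:
        return float(self._values[_INDEX[name]])

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(NUTRIENT_FIELDS, self._values)}

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return NutrientVector(self._values + other._values)

    def __mul__(self, scalar: float) -> "NutrientVector":
        s = float(scalar)
        if s < 0:
            raise ValueError("scaling factor must be nonnegative")
        return NutrientVector(self._values * s)

    __rmul__ = __mul__

    # -- comparison / misc -------------------------------------------------
    def allclose(self, other: "NutrientVector", rtol: float = 1e-9) -> bool:
        return bool(np.allclose(self._values, other._values, rtol=rtol, atol=1e-12))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NutrientVector) and bool(
            np.array_equal(self._values, other._values)
        )

    def __hash__(self):  # immutable, hash by content
        return hash(self._values.tobytes())

    def __repr__(self) -> str:
        nz = {k: v for k, v in self.as_dict().items() if v != 0}
        return f"NutrientVector({nz})"


ZERO = NutrientVector()
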