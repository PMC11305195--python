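"""Published worked-example adequacy tables for the Karnataka demonstrations.

Two packaged reference tables, as printed in the program documentation for the
Karnataka worked examples: the nutrient composition of a cost-optimized hot
cooked meal for children aged 3-6 y, and of an optimized take-home ration for
children aged 1-3 y.  Each row is (guideline value, optimized content,
printed percent of guideline).  Units follow the canonical nutrient schema.

``SELF_CONSISTENT`` lists the rows whose printed percentage agrees with
one-decimal division of the printed guideline/content pair; the remaining
rows were evidently computed from unrounded internal values and cannot be
reproduced from the printed inputs alone.
"""

from __future__ import annotations

# nutrient -> (guideline, content, printed percent of guideline)
HCM_CHILD_3_6Y: dict[str, tuple[float, float, float]] = {
    "energy_kcal": (400.0, 400.1, 100.0),
    "protein_g": (15.0, 17.0, 114.0),
    "fat_g": (15.0, 14.0, 94.0),
    "calcium_mg": (150.0, 110.8, 74.0),
    "fiber_g": (6.8, 5.1, 76.0),
    "folate_ug": (40.0, 75.2, 189.0),
    "iron_mg": (3.0, 3.7, 125.0),
    "magnesium_mg": (34.7, 79.4, 229.0),
    "vitamin_b3_mg": (2.7, 2.3, 87.0),
    "vitamin_b6_mg": (0.3, 0.2, 78.0),
    "vitamin_b2_mg": (0.4, 0.2, 53.0),
    "vitamin_b1_mg": (0.3, 0.2, 69.0),
    "vitamin_a_ug": (80.0, 128.0, 161.0),
    "vitamin_b12_ug": (0.7, 0.5, 77.0),
    "vitamin_c_mg": (9.0, 11.0, 122.0),
    "zinc_mg": (1.5, 2.1, 140.0),
}

THR_CHILD_1_3Y: dict[str, tuple[float, float, float]] = {
    "energy_kcal": (400.0, 400.0, 100.0),
    "protein_g": (15.0, 13.7, 91.3),
    "fat_g": (15.0, 13.5, 90.0),
    "calcium_mg": (135.0, 134.1, 99.3),
    "fiber_g": (5.6, 10.2, 183.8),
    "folate_ug": (35.0, 50.9, 145.4),
    "iron_mg": (2.0, 3.4, 170.0),
    "magnesium_mg": (24.3, 118.5, 487.1),
    "vitamin_a_ug": (60.0, 75.8, 126.3),
    "vitamin_b1_mg": (0.2, 0.4, 200.0),
    "vitamin_b12_ug": (0.3, 0.0, 0.0),
    "vitamin_b2_mg": (0.3, 0.3, 111.1),
    "vitamin_b3_mg": (2.0, 1.9, 95.0),
    "vitamin_b6_mg": (0.3, 0.2, 74.1),
    "vitamin_c_mg": (8.0, 0.4, 5.0),
    "zinc_mg": (1.0, 2.6, 260.0),
}

#: Rows reproducible to one decimal from the printed (guideline, content) pair.
SELF_CONSISTENT: dict[str, tuple[str, ...]] = {
    "thr_child_1_3y": (
        "energy_kcal",
        "protein_g",
        "fat_g",
        "calcium_mg",
        "folate_ug",
        "iron_mg",
        "vitamin_a_ug",
        "zinc_mg",
    ),
    "hcm_child_3_6y": ("energy_kcal", "zinc_mg"),
}
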