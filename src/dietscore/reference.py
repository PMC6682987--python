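"""Published ELANS summary statistics used as simulation defaults and worked examples.

The ELANS survey (Latin American Study of Nutrition and Health, eight urban
populations, n = 9218, ages 15-65) released population-level summaries --
per-country means and standard deviations of 2000-kcal-adjusted usual intake
for 17 dietary factors, pooled quintile means, per-country sample sizes, and
food-group consumption frequencies -- but no subject-level microdata.  Those
printed summaries are collected here verbatim: they parameterize the
synthetic-data generator (so simulated populations have the survey's marginal
structure) and serve as inputs to worked-example computations such as the
fifth-to-first-quintile intake ratios.

All intake values are on the 2000 kcal/day-adjusted scale, in each factor's
native unit (g/d, mg/d, or % of energy).
"""

from __future__ import annotations

# Per-country (mean, SD) of usual intake, 2000-kcal-adjusted, by factor.
# Keyed factor -> country -> (mean, sd).
COUNTRY_FACTOR_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "beans_legumes": {
        "Argentina": (2.52, 7.79), "Brazil": (59.34, 34.28), "Chile": (21.81, 29.28),
        "Colombia": (41.61, 24.13), "Costa Rica": (103.64, 56.40), "Ecuador": (47.95, 28.81),
        "Peru": (23.53, 17.79), "Venezuela": (24.81, 23.04),
    },
    "plant_omega3": {
        "Argentina": (0.32, 0.20), "Brazil": (0.10, 0.05), "Chile": (0.11, 0.06),
        "Colombia": (0.09, 0.04), "Costa Rica": (0.18, 0.09), "Ecuador": (0.12, 0.05),
        "Peru": (0.12, 0.05), "Venezuela": (0.10, 0.05),
    },
    "dietary_fiber": {
        "Argentina": (10.90, 3.36), "Brazil": (15.57, 4.65), "Chile": (16.88, 4.78),
        "Colombia": (17.31, 4.27), "Costa Rica": (21.98, 6.44), "Ecuador": (17.21, 3.83),
        "Peru": (17.73, 4.60), "Venezuela": (16.48, 4.51),
    },
    "vegetables": {
        "Argentina": (100.83, 49.52), "Brazil": (88.69, 70.17), "Chile": (171.68, 76.03),
        "Colombia": (89.57, 43.19), "Costa Rica": (146.88, 77.02), "Ecuador": (163.12, 61.53),
        "Peru": (107.76, 36.06), "Venezuela": (96.68, 40.04),
    },
    "milk": {
        "Argentina": (73.54, 80.59), "Brazil": (123.09, 120.26), "Chile": (93.84, 114.39),
        "Colombia": (172.96, 108.55), "Costa Rica": (86.03, 94.37), "Ecuador": (96.85, 67.73),
        "Peru": (42.16, 31.26), "Venezuela": (75.72, 68.52),
    },
    "fruits": {
        "Argentina": (75.02, 77.20), "Brazil": (83.81, 86.85), "Chile": (123.25, 89.66),
        "Colombia": (66.95, 70.25), "Costa Rica": (79.92, 86.93), "Ecuador": (83.25, 76.25),
        "Peru": (116.74, 85.40), "Venezuela": (27.30, 51.43),
    },
    "polyunsaturated_fat_pct": {
        "Argentina": (7.92, 2.16), "Brazil": (7.34, 1.92), "Chile": (6.67, 1.70),
        "Colombia": (7.24, 1.48), "Costa Rica": (7.83, 1.67), "Ecuador": (9.12, 1.81),
        "Peru": (7.21, 1.44), "Venezuela": (7.71, 1.98),
    },
    "fish": {
        "Argentina": (6.45, 14.23), "Brazil": (23.07, 29.36), "Chile": (15.71, 16.20),
        "Colombia": (15.11, 18.33), "Costa Rica": (22.50, 14.78), "Ecuador": (28.32, 20.27),
        "Peru": (28.46, 21.05), "Venezuela": (19.44, 19.69),
    },
    "nuts_seeds": {
        "Argentina": (0.82, 2.84), "Brazil": (1.22, 4.34), "Chile": (0.93, 4.38),
        "Colombia": (4.36, 16.28), "Costa Rica": (2.20, 7.74), "Ecuador": (3.70, 6.43),
        "Peru": (2.74, 4.38), "Venezuela": (0.47, 3.87),
    },
    "whole_grains": {
        "Argentina": (9.87, 16.99), "Brazil": (7.24, 21.10), "Chile": (8.02, 22.25),
        "Colombia": (9.38, 12.94), "Costa Rica": (14.32, 17.32), "Ecuador": (10.48, 17.54),
        "Peru": (12.29, 13.36), "Venezuela": (6.06, 10.29),
    },
    "sodium": {
        "Argentina": (2.60, 0.50), "Brazil": (2.96, 0.64), "Chile": (2.93, 0.58),
        "Colombia": (1.95, 0.51), "Costa Rica": (3.02, 0.56), "Ecuador": (4.52, 0.77),
        "Peru": (0.97, 0.24), "Venezuela": (3.10, 0.52),
    },
    "trans_fat_pct": {
        "Argentina": (1.00, 0.24), "Brazil": (1.33, 0.64), "Chile": (1.00, 0.28),
        "Colombia": (1.00, 0.26), "Costa Rica": (0.71, 0.23), "Ecuador": (0.70, 0.18),
        "Peru": (0.49, 0.18), "Venezuela": (0.96, 0.25),
    },
    "saturated_fat_pct": {
        "Argentina": (11.70, 2.38), "Brazil": (9.77, 2.32), "Chile": (10.80, 2.29),
        "Colombia": (10.62, 2.13), "Costa Rica": (8.74, 2.09), "Ecuador": (8.95, 1.93),
        "Peru": (6.49, 1.46), "Venezuela": (9.87, 2.02),
    },
    "unprocessed_red_meats": {
        "Argentina": (78.62, 34.26), "Brazil": (94.71, 43.48), "Chile": (57.42, 29.23),
        "Colombia": (71.07, 29.29), "Costa Rica": (49.39, 21.42), "Ecuador": (62.17, 25.67),
        "Peru": (29.30, 20.27), "Venezuela": (67.72, 26.56),
    },
    "sugar_sweetened_beverages": {
        "Argentina": (1092.90, 650.31), "Brazil": (611.65, 323.11), "Chile": (331.73, 240.66),
        "Colombia": (482.99, 227.95), "Costa Rica": (702.40, 351.13), "Ecuador": (677.22, 234.74),
        "Peru": (920.17, 325.93), "Venezuela": (597.92, 290.73),
    },
    "processed_meats": {
        "Argentina": (22.39, 12.36), "Brazil": (26.65, 20.49), "Chile": (29.77, 21.70),
        "Colombia": (15.51, 11.79), "Costa Rica": (23.40, 15.15), "Ecuador": (11.29, 9.98),
        "Peru": (6.72, 3.90), "Venezuela": (21.14, 14.08),
    },
    "cholesterol": {
        "Argentina": (346.85, 90.67), "Brazil": (278.40, 89.48), "Chile": (285.00, 100.98),
        "Colombia": (329.61, 95.06), "Costa Rica": (247.71, 97.14), "Ecuador": (257.37, 69.27),
        "Peru": (279.74, 75.04), "Venezuela": (270.26, 83.24),
    },
}

# Per-country achieved sample sizes (sums to 9218).
COUNTRY_SAMPLE_SIZES: dict[str, int] = {
    "Argentina": 1266, "Brazil": 2000, "Chile": 879, "Colombia": 1230,
    "Costa Rica": 798, "Ecuador": 800, "Peru": 1113, "Venezuela": 1132,
}

# Pooled first- and fifth-quintile means of 2000-kcal-adjusted usual intake.
# Inputs for the published fifth-to-first-quintile ratio worked examples
# (e.g. nuts and seeds 9.86/0.05 = 197.20).
QUINTILE_Q1_Q5_MEANS: dict[str, tuple[float, float]] = {
    "nuts_seeds": (0.05, 9.86),
    "whole_grains": (0.95, 34.74),
    "fruits": (15.57, 201.73),
    "vegetables": (53.75, 195.00),
    "fish": (5.37, 51.63),
    "beans_legumes": (13.76, 81.03),
    "milk": (18.69, 241.52),
    "polyunsaturated_fat_pct": (5.31, 10.19),
    "dietary_fiber": (11.20, 22.82),
    "plant_omega3": (0.05, 0.17),
    "sugar_sweetened_beverages": (268.08, 1178.17),
    "unprocessed_red_meats": (30.34, 114.13),
    "processed_meats": (5.97, 43.20),
    "saturated_fat_pct": (6.92, 12.68),
    "trans_fat_pct": (0.58, 1.44),
    "cholesterol": (186.10, 419.64),
    "sodium": (2.00, 3.45),
}

# Share of subjects consuming >= 15 g from each women's-diversity group on the
# first recall day, as published for the whole sample.  Groups without a
# published frequency default to 0.5 in the generator.
WDDS9_GROUP_PROBS: dict[str, float] = {
    "starchy_staples": 0.995,
    "meat_fish": 0.854,
    "other_fruits_vegetables": 0.822,
    "dark_green_leafy_vegetables": 0.069,
    "organ_meat": 0.029,
    "vitamin_a_fruits_vegetables": 0.5,
    "eggs": 0.5,
    "legumes_nuts_seeds": 0.5,
    "milk_products": 0.5,
}

# Analogous defaults for the household-style (HDDS) grouping; only the groups
# with a clear published counterpart carry a survey frequency.
HDDS9_GROUP_PROBS: dict[str, float] = {
    "cereals": 0.995,
    "white_roots_tubers": 0.5,
    "vegetables": 0.822,
    "fruits": 0.822,
    "meat_poultry_offal": 0.854,
    "fish_seafood": 0.5,
    "eggs": 0.5,
    "pulses_legumes_nuts": 0.5,
    "milk_products": 0.5,
}
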