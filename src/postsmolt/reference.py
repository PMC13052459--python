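"""Published study-design summary used as simulator defaults.

These are the printed per-river, per-year cohort descriptors of the Moray
Firth post-smolt telemetry study (tag counts, body size, raw minimum
migration-success percentages) together with a few study-wide constants
(tag mass and delay range, coastal receiver spacing, sentinel detection
range). They parameterise the synthetic-data generator and support simple
summary arithmetic; they are design inputs, not computed results.
"""

from __future__ import annotations

import pandas as pd

# one row per tagged river x year cohort
COHORTS = pd.DataFrame(
    [
        # river, year, n_tagged, fl_mean, fl_sd, mass_mean, mass_sd,
        # river_success_pct, inlet_n, inlet_pct, coastal_n, coastal_pct
        ("Shin",     2019, 100, 136.2, 4.83, 24.2, 2.50, 92, 68, 76, 52, 77),
        ("Shin",     2021, 100, 140.2, 6.63, 25.7, 3.60, 82, 50, 76, 40, 80),
        ("Cassley",  2021,  48, 140.1, 6.26, 25.2, 3.91, 68, 24, 80, 18, 75),
        ("Oykel",    2019, 149, 137.0, 7.24, 25.3, 3.94, 70, 67, 69, 48, 72),
        ("Oykel",    2021, 100, 140.0, 7.47, 25.7, 4.28, 84, 66, 84, 43, 65),
        ("Conon",    2019,  99, 139.4, 5.39, 26.6, 3.35, 90, 33, 72, 18, 54),
        ("Conon",    2021, 100, 145.4, 8.56, 30.0, 5.53, 65, 47, 75, 37, 79),
        ("Ness",     2019, 100, 140.3, 10.91, 28.8, 6.73, 10,  8, 89,  8, 100),
        ("Ness",     2021, 120, 139.8, 7.88, 28.2, 5.10, 20, 17, 79, 12, 71),
        ("Findhorn", 2019, 100, 135.5, 6.05, 23.7, 3.58, 44, 54, 83, 38, 70),
        ("Findhorn", 2021,  93, 137.2, 6.62, 23.7, 3.16, 86, 55, 67, 34, 62),
        ("Spey",     2019, 150, 134.5, 3.59, 24.0, 2.46, 61, None, None, 56, 37),
        ("Spey",     2021, 100, 135.5, 4.10, 24.3, 2.37, 41, None, None, 34, 65),
        ("Deveron",  2019, 100, 133.6, 5.04, 23.5, 2.66, 51, 33, 87, None, None),
        ("Deveron",  2021, 100, 137.1, 4.83, 25.1, 2.90, 74, 47, 64, None, None),
    ],
    columns=["river", "year", "n_tagged", "fl_mean_mm", "fl_sd_mm",
             "mass_mean_g", "mass_sd_g", "river_success_pct",
             "inlet_n", "inlet_pct", "coastal_n", "coastal_pct"],
)

# study-wide printed counts of fish entering marine waters
MARINE_ENTRIES = {2019: 431, 2021: 467}

TAG_MASS_G = 1.5
TAG_DELAY_RANGE_S = (18.0, 35.0)
COASTAL_RECEIVER_SPACING_M = 603.0
SENTINEL_D50_RANGE_M = (293.0, 354.0)
COASTAL_ARRAY_N_RECEIVERS = 127


def cohort_summary() -> dict:
    """Arithmetic summaries of the printed cohort table."""
    inlet = COHORTS["inlet_pct"].dropna().astype(float)
    return {
        "n_cohorts": int(len(COHORTS)),
        "total_tagged": int(COHORTS["n_tagged"].sum()),
        "mean_cohort_size": float(COHORTS["n_tagged"].mean()),
        "n_inlet_cells": int(len(inlet)),
        "mean_inlet_success_pct": float(inlet.mean()),
        "marine_entries_total": int(sum(MARINE_ENTRIES.values())),
    }
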