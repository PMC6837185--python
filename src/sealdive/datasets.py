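"""Published Kleinsee study tables, shipped as in-memory fixtures.

Morphometrics, first-trip effort statistics (32 lactating Cape fur seals,
Kleinsee colony, austral winters 2006-2008) and the 2006 blood/muscle
chemistry panel used for body oxygen-store estimation. These are the
printed per-seal values; derived quantities (BCI, Bv, O2 stores, MCHC) are
recomputed by the pipeline rather than read from here.
"""

from __future__ import annotations

import pandas as pd

# Kleinsee colony, South Africa
KLEINSEE_LAT = -29.5695
KLEINSEE_LON = 16.9967

# seal, SL (cm), mass (kg), AG (cm), FFL (cm), printed BCI (kg),
# trip start, trip duration (days), dives (n), dive rate (m/h), benthic (%)
_MORPHOMETRICS = [
    (1, 132, 48.8, 92, 40.0, 2.18, "2006-07-02", 2.6, 762, 728, 0),
    (2, 129, 45.0, 90, None, 3.70, "2006-07-05", 5.2, 1406, 1086, 1),
    (3, 136, 47.5, 85, 38.0, 6.52, "2006-07-06", 8.5, 1536, 1263, 3),
    (4, 143, 53.0, 89, 44.0, 6.34, "2006-07-06", 2.1, 460, 1162, 22),
    (5, 139, 57.5, 102, None, -1.20, "2006-07-04", 1.7, 161, 827, 24),
    (6, 136, 54.5, 94, 49.0, -0.48, "2006-07-06", 7.3, 1480, 1000, 0),
    (7, 131, 59.0, 99, 44.0, -8.78, "2006-07-07", 10.7, 1289, 1500, 8),
    (8, 143, 58.0, 97, None, 1.34, "2006-07-05", 9.1, 1478, 913, 15),
    (9, 110, 34.5, 83, 40.0, -0.25, "2006-07-06", 4.1, 1588, 992, 6),
    (10, 137, 52.5, 89, 47.0, 2.28, "2006-07-05", 8.7, 2196, 1035, 0),
    (11, 125, 51.8, 92, 40.0, -6.14, "2007-06-23", 4.0, 908, 1171, 18),
    (12, 140, 59.6, 95, 40.0, -2.54, "2007-06-25", 3.2, 675, 1360, 14),
    (13, 138, 52.4, 92, 42.0, 3.14, "2007-06-25", 5.7, 755, 1012, 4),
    (14, 125, 47.6, 84, 43.0, -1.94, "2007-06-26", 5.1, 1288, 1554, 9),
    (15, 144, 54.0, 87, 45.0, 6.12, "2007-06-25", 4.4, 843, 1012, 11),
    (16, 146, 78.4, 108, 46.0, -16.80, "2007-06-28", 4.9, 1677, 1554, 11),
    (17, 137, 53.2, 89, 44.0, 1.58, "2007-06-27", 7.1, 1366, 1208, 0),
    (18, 135, 54.4, 92, 42.0, -1.14, "2007-06-28", 8.9, 335, 1042, 19),
    (19, 140, 60.0, 97, 42.0, -2.94, "2007-06-27", 2.1, 1095, 1662, 80),
    (20, 148, 58.6, 94, 46.0, 4.16, "2008-06-24", 5.4, 445, 1014, 10),
    (21, 130, 46.2, 82, 40.0, 3.26, "2008-06-21", 2.0, 991, 923, 19),
    (22, 135, 49.2, 85, 41.0, 3.68, "2008-06-20", 5.2, 592, 1185, 5),
    (23, 125, 41.6, 83, 38.0, 3.68, "2008-06-21", 4.0, 1448, 568, 15),
    (24, 152, 68.4, 94, 43.0, -2.60, "2008-06-21", 14.5, 2317, 865, 7),
    (25, 136, 53.8, 89, 40.0, -0.16, "2008-06-24", 7.8, 547, 1306, 6),
    (26, 137, 63.4, 90, 43.0, -8.62, "2008-06-23", 2.7, 545, 1453, 34),
    (27, 135, 59.0, 80, 39.0, -6.12, "2008-06-20", 3.8, 1288, 1230, 43),
    (28, 137, 56.2, 88, 41.0, -1.42, "2008-06-22", 3.5, 333, 947, 56),
    (29, 130, 49.0, 84, 40.0, 0.08, "2008-06-23", 6.3, 1647, 1019, 2),
    (30, 134, 50.2, 85, 38.0, 2.30, "2008-06-23", 4.6, 795, 742, 4),
    (31, 139, 53.4, 89, 43.0, 2.90, "2008-06-23", 3.2, 556, 962, 32),
    (32, 140, 49.2, 81, 41.0, 7.86, "2008-06-22", 4.5, 1035, 1630, 20),
]

# seal, Pv (ml/kg), Bv (ml/kg), Hct (%), Hb (g/dl), Mb (g/100 g), O2 stores (ml/kg)
# 2006 animals; no panel was obtained for seal 8.
_BLOOD_CHEMISTRY = [
    (1, 36, 85, 58, 17.10, 4.91, 46.5),
    (2, 34, 71, 52, 14.95, 4.18, 38.7),
    (3, 48, 104, 54, 16.26, 4.58, 47.4),
    (4, 36, 88, 59, 16.78, 4.45, 44.7),
    (5, 32, 72, 56, 16.80, 4.66, 42.8),
    (6, 17, 37, 55, 16.27, 4.64, 36.3),
    (7, 35, 78, 55, 16.27, 4.61, 43.0),
    (9, 47, 102, 54, 16.12, 4.79, 47.8),
    (10, 36, 79, 54, 16.15, 4.44, 42.3),
]


def kleinsee_morphometrics() -> pd.DataFrame:
    """Per-seal morphometrics and first-trip effort statistics.

    Returns a DataFrame indexed by seal id with columns ``sl_cm``,
    ``mass_kg``, ``ag_cm``, ``ffl_cm`` (NaN for the three animals without a
    fore-flipper measurement), ``bci_printed_kg``, ``trip_start``,
    ``trip_days``, ``n_dives``, ``dive_rate_m_h``, ``benthic_pct`` and
    ``year``.
    """
    df = pd.DataFrame(
        _MORPHOMETRICS,
        columns=[
            "seal",
            "sl_cm",
            "mass_kg",
            "ag_cm",
            "ffl_cm",
            "bci_printed_kg",
            "trip_start",
            "trip_days",
            "n_dives",
            "dive_rate_m_h",
            "benthic_pct",
        ],
    ).set_index("seal")
    df["trip_start"] = pd.to_datetime(df["trip_start"])
    df["year"] = df["trip_start"].dt.year
    df["ffl_cm"] = df["ffl_cm"].astype(float)
    return df


def kleinsee_blood_chemistry() -> pd.DataFrame:
    """2006 blood and muscle chemistry panel (nine seals).

    Columns: ``pv_ml_kg``, ``bv_printed_ml_kg``, ``hct_pct``, ``hb_g_dl``,
    ``mb_g_100g`` and ``o2_printed_ml_kg``. Blood volume and total oxygen
    stores carry the ``printed`` suffix because the pipeline recomputes both
    from the primary measurements.
    """
    return pd.DataFrame(
        _BLOOD_CHEMISTRY,
        columns=[
            "seal",
            "pv_ml_kg",
            "bv_printed_ml_kg",
            "hct_pct",
            "hb_g_dl",
            "mb_g_100g",
            "o2_printed_ml_kg",
        ],
    ).set_index("seal")
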