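"""Published reference data for the pakchoi pot experiment.

The package's defaults emulate a greenhouse pot experiment on pakchoi
(*Brassica campestris* ssp. *chinensis* L.) with four nitrogen levels
(an unfertilized control plus three urea doses) sampled at six dates
over a 42-day cycle.  The summary statistics printed in the study's
report — per-treatment shoot dry biomass and shoot N concentration
(mean ± SD, n = 3), the per-date critical N concentrations, the
resulting NNI table, and the 23-feature screening result — are bundled
here as machine-readable constants.  They serve as inputs for NNI
reproduction and as the calibration the synthetic generator targets.
"""

from __future__ import annotations

import pandas as pd

#: Treatment labels and their N dose in g N per pot.
TREATMENT_DOSES = {"CK": 0.0, "T1": 0.134, "T2": 0.163, "T3": 0.191}

#: Sampling dates, days after the first N application.
SAMPLING_DAYS = [7, 14, 21, 28, 35, 42]

# Shoot dry biomass, g per plant (mean, SD), by treatment and day.
BIOMASS_MEAN = {
    "CK": [0.065, 0.161, 0.186, 0.338, 0.479, 0.617],
    "T1": [0.067, 0.174, 0.293, 0.580, 0.973, 1.363],
    "T2": [0.080, 0.189, 0.306, 0.574, 0.994, 1.280],
    "T3": [0.079, 0.215, 0.440, 0.620, 0.970, 1.282],
}
BIOMASS_SD = {
    "CK": [0.007, 0.006, 0.008, 0.012, 0.037, 0.037],
    "T1": [0.004, 0.019, 0.010, 0.023, 0.019, 0.032],
    "T2": [0.004, 0.023, 0.014, 0.018, 0.051, 0.025],
    "T3": [0.010, 0.011, 0.025, 0.014, 0.017, 0.027],
}

# Shoot N concentration, g per kg dry weight (mean, SD).
NCONC_MEAN = {
    "CK": [43.30, 39.70, 39.07, 30.80, 20.50, 20.50],
    "T1": [57.50, 61.27, 69.63, 67.30, 72.70, 83.77],
    "T2": [57.63, 62.20, 74.87, 71.97, 81.87, 88.07],
    "T3": [60.57, 64.00, 73.30, 76.63, 79.47, 88.80],
}
NCONC_SD = {
    "CK": [2.31, 2.76, 1.59, 1.57, 1.08, 0.79],
    "T1": [0.26, 1.01, 1.90, 0.17, 2.66, 2.57],
    "T2": [0.85, 1.23, 2.25, 0.99, 1.65, 2.67],
    "T3": [1.27, 0.85, 4.98, 0.50, 0.74, 2.11],
}

#: Critical N concentration (g/kg DW) at each sampling date, as published.
NC_VALUES = dict(zip(SAMPLING_DAYS, [56.08, 63.36, 69.16, 72.14, 76.44, 79.46]))

#: Published NNI table (2 decimals) by treatment and day.  Note: the
#: CK day-21 cell does not reproduce from the printed inputs
#: (39.07 / 69.16 = 0.56, printed as 0.57).
PUBLISHED_NNI = {
    "CK": [0.77, 0.63, 0.57, 0.43, 0.27, 0.26],
    "T1": [1.03, 0.97, 1.01, 0.93, 0.95, 1.05],
    "T2": [1.03, 0.98, 1.08, 1.00, 1.07, 1.11],
    "T3": [1.08, 1.01, 1.06, 1.06, 1.04, 1.12],
}

#: The published screening result: 23 features significant at every
#: sampling date (16 color, 3 texture, 4 morphology).
PRESET_23 = [
    # color: mean and median of R, G, B, L, b, H, S, V
    "R_mean", "R_median",
    "G_mean", "G_median",
    "B_mean", "B_median",
    "L_mean", "L_median",
    "b_mean", "b_median",
    "H_mean", "H_median",
    "S_mean", "S_median",
    "V_mean", "V_median",
    # texture
    "homogeneity", "energy", "ASM",
    # morphology
    "contour_area", "hull_area", "r", "equivalent_diameter",
]

PRESETS = {"paper23": PRESET_23}


def growth_table() -> pd.DataFrame:
    """Reference growth records as a tidy table.

    Returns one row per treatment x day with columns ``treatment``,
    ``dose``, ``day``, ``biomass_dm``, ``biomass_sd``, ``n_conc``,
    ``n_conc_sd`` (biomass in g/plant, N concentration in g/kg DW).
    """
    rows = []
    for trt, dose in TREATMENT_DOSES.items():
        for i, day in enumerate(SAMPLING_DAYS):
            rows.append({
                "treatment": trt,
                "dose": dose,
                "day": day,
                "biomass_dm": BIOMASS_MEAN[trt][i],
                "biomass_sd": BIOMASS_SD[trt][i],
                "n_conc": NCONC_MEAN[trt][i],
                "n_conc_sd": NCONC_SD[trt][i],
            })
    return pd.DataFrame(rows)


def published_nni_table() -> pd.DataFrame:
    """Published NNI values as a tidy table (treatment, day, nni)."""
    rows = [
        {"treatment": trt, "day": day, "nni": PUBLISHED_NNI[trt][i]}
        for trt in PUBLISHED_NNI
        for i, day in enumerate(SAMPLING_DAYS)
    ]
    return pd.DataFrame(rows)


def preset_features(name: str = "paper23") -> list[str]:
    """Return a named published feature preset (a list of feature names)."""
    try:
        return list(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
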