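"""Reference cohort parameters for the five-group ALS FD study design.

These constants parameterize the synthetic cohort generator: group sizes,
demographics and clinical-measure distributions of a neurological-control
group and four ALS phenotype subgroups (ALS with frontotemporal dementia,
UMN-predominant ALS with and without corticospinal-tract hyperintensity,
and classic ALS), together with the group-wise means and standard
deviations of the nine white-matter fractal-dimension outcomes
(skeleton / surface / general structure x left / right / whole brain).

Version 1 of this table; treat edits as a change of study conditions.
"""

from __future__ import annotations

GROUPS = ["Control", "ALS-FTD", "ALS-CST+", "ALS-CSTminus", "ALS-Cl"]

#: Subjects per group (total n = 97).
GROUP_SIZES = {
    "Control": 11,
    "ALS-FTD": 20,
    "ALS-CST+": 20,
    "ALS-CSTminus": 24,
    "ALS-Cl": 22,
}

#: Age, years: mean and SD per group.
AGE_MEAN = {
    "Control": 51.7,
    "ALS-FTD": 66.7,
    "ALS-CST+": 52.9,
    "ALS-CSTminus": 58.0,
    "ALS-Cl": 57.4,
}
AGE_SD = {
    "Control": 16.6,
    "ALS-FTD": 9.9,
    "ALS-CST+": 11.5,
    "ALS-CSTminus": 11.5,
    "ALS-Cl": 11.5,
}

#: Fraction of male subjects per group.
MALE_FRACTION = {
    "Control": 8 / 11,
    "ALS-FTD": 7 / 20,
    "ALS-CST+": 13 / 20,
    "ALS-CSTminus": 14 / 24,
    "ALS-Cl": 12 / 22,
}

#: ALSFRS-R (0-48, lower = more impaired): mean and SD; not scored in controls.
ALSFRS_MEAN = {
    "ALS-FTD": 30.5,
    "ALS-CST+": 34.9,
    "ALS-CSTminus": 35.0,
    "ALS-Cl": 37.2,
}
ALSFRS_SD = {
    "ALS-FTD": 7.2,
    "ALS-CST+": 8.0,
    "ALS-CSTminus": 8.6,
    "ALS-Cl": 8.7,
}

#: Disease duration, months: median and quartiles; generated log-normally.
DURATION_MEDIAN = {
    "ALS-FTD": 34.0,
    "ALS-CST+": 13.0,
    "ALS-CSTminus": 35.5,
    "ALS-Cl": 13.0,
}
DURATION_Q1 = {
    "ALS-FTD": 18.8,
    "ALS-CST+": 9.5,
    "ALS-CSTminus": 17.8,
    "ALS-Cl": 9.0,
}
DURATION_Q3 = {
    "ALS-FTD": 45.0,
    "ALS-CST+": 18.3,
    "ALS-CSTminus": 55.0,
    "ALS-Cl": 52.0,
}

#: El Escorial category probabilities (1=possible .. 4=definite) per group.
EES_PROBS = {
    "ALS-FTD": [0.35, 0.10, 0.35, 0.20],
    "ALS-CST+": [0.50, 0.20, 0.25, 0.05],
    "ALS-CSTminus": [0.75, 0.08, 0.13, 0.04],
    "ALS-Cl": [0.15, 0.30, 0.40, 0.15],
}

#: FD outcome means per group: {outcome: {group: mean}}.
FD_MEAN = {
    "fd_skeleton_lh": {"Control": 2.407, "ALS-FTD": 2.404, "ALS-CST+": 2.420,
                       "ALS-CSTminus": 2.406, "ALS-Cl": 2.412},
    "fd_skeleton_rh": {"Control": 2.409, "ALS-FTD": 2.394, "ALS-CST+": 2.420,
                       "ALS-CSTminus": 2.400, "ALS-Cl": 2.403},
    "fd_skeleton_wb": {"Control": 2.487, "ALS-FTD": 2.469, "ALS-CST+": 2.501,
                       "ALS-CSTminus": 2.480, "ALS-Cl": 2.484},
    "fd_surface_lh": {"Control": 2.462, "ALS-FTD": 2.468, "ALS-CST+": 2.467,
                      "ALS-CSTminus": 2.464, "ALS-Cl": 2.471},
    "fd_surface_rh": {"Control": 2.467, "ALS-FTD": 2.465, "ALS-CST+": 2.472,
                      "ALS-CSTminus": 2.465, "ALS-Cl": 2.468},
    "fd_surface_wb": {"Control": 2.549, "ALS-FTD": 2.551, "ALS-CST+": 2.557,
                      "ALS-CSTminus": 2.547, "ALS-Cl": 2.557},
    "fd_general_lh": {"Control": 2.582, "ALS-FTD": 2.572, "ALS-CST+": 2.590,
                      "ALS-CSTminus": 2.582, "ALS-Cl": 2.590},
    "fd_general_rh": {"Control": 2.598, "ALS-FTD": 2.583, "ALS-CST+": 2.603,
                      "ALS-CSTminus": 2.575, "ALS-Cl": 2.581},
    "fd_general_wb": {"Control": 2.633, "ALS-FTD": 2.618, "ALS-CST+": 2.638,
                      "ALS-CSTminus": 2.625, "ALS-Cl": 2.629},
}

#: FD outcome SDs per group: {outcome: {group: sd}}.
FD_SD = {
    "fd_skeleton_lh": {"Control": 0.018, "ALS-FTD": 0.030, "ALS-CST+": 0.022,
                       "ALS-CSTminus": 0.027, "ALS-Cl": 0.022},
    "fd_skeleton_rh": {"Control": 0.021, "ALS-FTD": 0.023, "ALS-CST+": 0.021,
                       "ALS-CSTminus": 0.025, "ALS-Cl": 0.019},
    "fd_skeleton_wb": {"Control": 0.018, "ALS-FTD": 0.020, "ALS-CST+": 0.024,
                       "ALS-CSTminus": 0.023, "ALS-Cl": 0.017},
    "fd_surface_lh": {"Control": 0.018, "ALS-FTD": 0.020, "ALS-CST+": 0.015,
                      "ALS-CSTminus": 0.019, "ALS-Cl": 0.013},
    "fd_surface_rh": {"Control": 0.024, "ALS-FTD": 0.017, "ALS-CST+": 0.013,
                      "ALS-CSTminus": 0.022, "ALS-Cl": 0.014},
    "fd_surface_wb": {"Control": 0.017, "ALS-FTD": 0.020, "ALS-CST+": 0.013,
                      "ALS-CSTminus": 0.019, "ALS-Cl": 0.014},
    "fd_general_lh": {"Control": 0.054, "ALS-FTD": 0.044, "ALS-CST+": 0.035,
                      "ALS-CSTminus": 0.044, "ALS-Cl": 0.041},
    "fd_general_rh": {"Control": 0.020, "ALS-FTD": 0.016, "ALS-CST+": 0.033,
                      "ALS-CSTminus": 0.048, "ALS-Cl": 0.050},
    "fd_general_wb": {"Control": 0.013, "ALS-FTD": 0.013, "ALS-CST+": 0.015,
                      "ALS-CSTminus": 0.015, "ALS-Cl": 0.015},
}

#: FD change per year of age shared by all outcomes in the generator.
DEFAULT_AGE_SLOPE = -0.0005

#: SD of the gender-specific random intercept on FD.
DEFAULT_GENDER_SD = 0.005

#: Rank coupling between ALSFRS-R and whole-brain skeleton FD.
DEFAULT_ALSFRS_COUPLING = 0.431
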