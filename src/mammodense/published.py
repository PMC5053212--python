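"""Reference cohort characteristics from the motivating case-case study.

Printed contingency counts of the primary study sample (394 interval and
1009 screen-detected invasive breast cancers from the Stockholm-Gotland
screening region), used as worked-example inputs: re-deriving the published
within-group percentages from these counts exercises the summary-table
machinery, and the published effect sizes double as generative defaults for
the synthetic cohort.

Each entry maps a characteristic to ``{level: (IC count, SC count)}``;
percentages in the source table are percent of non-missing within the
detection-mode group, rounded to the nearest integer.
"""

#: Contingency counts by detection mode (IC, SC).
REFERENCE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "menopausal": {"yes": (297, 794), "no": (71, 151)},
    "hrt": {"no": (280, 802), "yes": (93, 156)},
    "oc_use": {"no": (78, 239), "yes": (300, 742)},
    "family_history": {"no": (284, 762), "yes": (84, 162)},
    "lymph_node": {"no": (356, 960), "yes": (37, 45)},
    "grade": {"1": (35, 147), "2": (109, 323), "3": (75, 127)},
    "er": {"negative": (57, 72), "positive": (239, 659)},
    "pr": {"negative": (109, 201), "positive": (181, 520)},
}

#: Published within-group percentages for selected rows (IC %, SC %),
#: as printed in the study's characteristics table.
REFERENCE_PERCENTAGES: dict[tuple[str, str], tuple[int, int]] = {
    ("menopausal", "yes"): (81, 84),
    ("hrt", "yes"): (25, 16),
    ("oc_use", "yes"): (79, 76),
    ("family_history", "yes"): (23, 18),
    ("lymph_node", "yes"): (9, 4),
    ("grade", "3"): (34, 21),
    ("er", "negative"): (19, 10),
}

#: Published per-SD odds ratios (final model) and square-root-scale
#: tumor-size slopes, used as the simulator's generative defaults.
REFERENCE_EFFECTS = {
    "or_f40": 1.32,          # gradient-skewness feature, IC vs SC
    "or_f21": 1.20,          # eccentricity feature, IC vs SC
    "beta_sc_f40": 0.20,     # sqrt tumor size per SD, screen-detected
    "beta_ic_f21": -0.18,    # sqrt tumor size per SD, interval
}
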