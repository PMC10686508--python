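"""Reference values: the published iterative meta-analysis tables.

One row per chain step: prior (mean, SD), likelihood (mean, SEM),
posterior (mean, SD), 95% credible interval and Bayes factor, all kept as
the printed strings so tests can respect each value's printed precision.
Step-0 rows have no posterior (the first study is the chain's prior); its
BF uses the vague prior scale in ``STEP0_SCALE``.

The age / reaction-time likelihood column was typeset garbled in the
original report (it duplicates the posterior credible interval); those
likelihoods were reconstructed by inverting the conjugate update from the
printed prior/posterior sequence and are marked ``reconstructed``.
"""

# (contrast, outcome, step, study, prior_mean, prior_sd, lik_mean, lik_sem,
#  post_mean, post_sd, ci_lo, ci_hi, bf, note)
ROWS = [
    # --- age / percent correct ---
    ("age", "percent_correct", 0, "Marshall", None, None, "4.83", "1.64",
     None, None, None, None, "15.99", "bf_directional"),
    ("age", "percent_correct", 1, "Study 1", "4.83", "1.64", "4.35", "2.42",
     "4.68", "1.36", "2.02", "7.34", "1.59", ""),
    ("age", "percent_correct", 2, "Study 2A", "4.68", "1.36", "1.29", "2.12",
     "3.70", "1.14", "1.46", "5.94", "0.58", ""),
    ("age", "percent_correct", 3, "Study 2B", "3.70", "1.14", "-1.98", "2.06",
     "2.37", "1.00", "0.41", "4.33", "0.78", ""),
    # --- age / reaction time (likelihoods reconstructed) ---
    ("age", "rt_ms", 0, "Marshall", None, None, "-441.28", "109.07",
     None, None, None, None, "3.77", ""),
    ("age", "rt_ms", 1, "Study 1", "-441.28", "109.07", "-155.70", "71.44",
     "-241.43", "59.76", "-358.56", "-124.30", "2.64", "reconstructed"),
    ("age", "rt_ms", 2, "Study 2A", "-241.43", "59.76", "-88.82", "60.03",
     "-165.46", "42.35", "-248.47", "-82.44", "1.22", "reconstructed"),
    ("age", "rt_ms", 3, "Study 2B", "-165.46", "42.35", "-75.51", "46.80",
     "-124.96", "31.40", "-186.50", "-63.42", "1.33", "reconstructed"),
    # --- stress / percent correct ---
    ("stress", "percent_correct", 0, "Marshall", None, None, "3.50", "1.62",
     None, None, None, None, "2.54", ""),
    ("stress", "percent_correct", 1, "Study 1", "3.50", "1.62", "5.77", "2.35",
     "4.23", "1.33", "1.62", "6.85", "2.36", ""),
    ("stress", "percent_correct", 2, "Study 2A", "4.23", "1.33", "3.79", "2.2",
     "4.11", "1.14", "1.88", "6.35", "1.55", ""),
    ("stress", "percent_correct", 3, "Study 2B", "4.11", "1.14", "-1.18", "2.07",
     "2.88", "1.00", "0.93", "4.84", "0.61", ""),
    # --- stress / reaction time ---
    ("stress", "rt_ms", 0, "Marshall", None, None, "62.33", "158.09",
     None, None, None, None, "0.96", ""),
    ("stress", "rt_ms", 1, "Study 1", "62.33", "158.09", "-146.53", "72.13",
     "-110.54", "65.62", "-239.16", "18.08", "1.27", ""),
    ("stress", "rt_ms", 2, "Study 2A", "-110.54", "65.62", "64.12", "59.29",
     "-14.38", "43.99", "-100.61", "71.85", "1.00", ""),
    ("stress", "rt_ms", 3, "Study 2B", "-14.38", "43.99", "2.63", "48.69",
     "-6.73", "32.64", "-70.72", "57.25", "0.81", ""),
    # --- interaction / percent correct ---
    ("interaction", "percent_correct", 0, "Marshall", None, None, "-12.55", "2.85",
     None, None, None, None, "50.86", ""),
    ("interaction", "percent_correct", 1, "Study 1", "-12.55", "2.85", "1.53", "4.65",
     "-8.70", "2.43", "-13.47", "-3.94", "0.62", ""),
    ("interaction", "percent_correct", 2, "Study 2A", "-8.70", "2.43", "-1.54", "4.23",
     "-6.92", "2.11", "-11.05", "-2.79", "0.92", ""),
    ("interaction", "percent_correct", 3, "Study 2B", "-6.92", "2.11", "6.39", "4.23",
     "-4.28", "1.89", "-7.98", "-0.58", "1.06", ""),
    # --- interaction / reaction time ---
    ("interaction", "rt_ms", 0, "Marshall", None, None, "-47.75", "254.72",
     None, None, None, None, "1.00", ""),
    ("interaction", "rt_ms", 1, "Study 1", "-47.75", "254.72", "104.80", "138.22",
     "70.10", "121.49", "-168.01", "308.22", "0.99", ""),
    ("interaction", "rt_ms", 2, "Study 2A", "70.10", "121.49", "93.36", "123.58",
     "81.53", "86.64", "-88.27", "251.33", "0.74", ""),
    ("interaction", "rt_ms", 3, "Study 2B", "81.53", "86.64", "-19.04", "96.41",
     "36.60", "64.44", "-89.70", "162.90", "0.62", ""),
    # --- stress within young / percent correct ---
    ("stress_within_young", "percent_correct", 0, "Marshall", None, None,
     "-2.39", "1.88", None, None, None, None, "0.71", ""),
    ("stress_within_young", "percent_correct", 1, "Study 1", "-2.39", "1.88",
     "6.13", "3.12", "-0.13", "1.61", "-3.28", "3.03", "1.20", ""),
    ("stress_within_young", "percent_correct", 2, "Study 2A", "-0.13", "1.61",
     "3.16", "3.06", "0.59", "1.42", "-2.21", "3.38", "1.00", ""),
    ("stress_within_young", "percent_correct", 3, "Study 2B", "0.59", "1.42",
     "1.79", "3.60", "0.75", "1.32", "-1.85", "3.34", "0.93", ""),
    # --- stress within young / reaction time ---
    ("stress_within_young", "rt_ms", 0, "Marshall", None, None,
     "-87.32", "78.59", None, None, None, None, "1.00", ""),
    ("stress_within_young", "rt_ms", 1, "Study 1", "-87.32", "78.59",
     "-111.89", "109.76", "-95.65", "63.90", "-220.89", "29.60", "1.00", ""),
    ("stress_within_young", "rt_ms", 2, "Study 2A", "-95.65", "63.90",
     "121.94", "82.12", "-13.59", "50.43", "-112.44", "85.26", "1.02", ""),
    ("stress_within_young", "rt_ms", 3, "Study 2B", "-13.59", "50.43",
     "-25.33", "65.47", "-17.96", "39.95", "-96.27", "60.35", "0.86", ""),
    # --- stress within older / percent correct ---
    ("stress_within_older", "percent_correct", 0, "Marshall", None, None,
     "9.39", "2.01", None, None, None, None, ">100", "bf_directional"),
    ("stress_within_older", "percent_correct", 1, "Study 1", "9.39", "2.01",
     "5.39", "3.26", "8.29", "1.71", "4.93", "11.64", "1.43", ""),
    ("stress_within_older", "percent_correct", 2, "Study 2A", "8.29", "1.71",
     "4.53", "2.83", "7.28", "1.47", "4.4", "10.15", "1.23", ""),
    ("stress_within_older", "percent_correct", 3, "Study 2B", "7.28", "1.47",
     "-4.15", "2.14", "3.62", "1.21", "1.25", "5.99", "1.94", ""),
    # --- stress within older / reaction time ---
    ("stress_within_older", "rt_ms", 0, "Marshall", None, None,
     "102.87", "209.13", None, None, None, None, "0.99", ""),
    ("stress_within_older", "rt_ms", 1, "Study 1", "102.87", "209.13",
     "-185.66", "75.62", "-152.3", "71.11", "-291.68", "-12.92", "2.15", ""),
    ("stress_within_older", "rt_ms", 2, "Study 2A", "-152.3", "71.11",
     "-2.73", "93.16", "-97.23", "56.53", "-208.03", "13.56", "1.00", ""),
    ("stress_within_older", "rt_ms", 3, "Study 2B", "-97.23", "56.53",
     "30.59", "69.27", "-46.14", "43.79", "-131.98", "39.7", "0.98", ""),
]

#: Vague prior SD used for each chain's step-0 Bayes factor (half the
#: assumed maximum plausible effect, as stated in the table footnotes /
#: printed prior column).
STEP0_SCALE = {
    ("age", "percent_correct"): 5.0,
    ("age", "rt_ms"): 50.0,
    ("stress", "percent_correct"): 5.0,
    ("stress", "rt_ms"): 50.0,
    ("interaction", "percent_correct"): 2.5,
    ("interaction", "rt_ms"): 25.0,
    ("stress_within_young", "percent_correct"): 5.0,
    ("stress_within_young", "rt_ms"): 12.5,
    ("stress_within_older", "percent_correct"): 12.5,
    ("stress_within_older", "rt_ms"): 37.5,
}

#: The Bayes-factor cells asserted numerically (the remaining step-0 cells
#: print rounded inputs whose BF is checked directionally only).
BF_CELLS = [
    ("age", "rt_ms", 0, 3.77),
    ("age", "percent_correct", 1, 1.59),
    ("age", "percent_correct", 2, 0.58),
    ("age", "percent_correct", 3, 0.78),
    ("age", "rt_ms", 1, 2.64),
    ("stress", "percent_correct", 0, 2.54),
    ("stress", "percent_correct", 1, 2.36),
    ("stress", "percent_correct", 2, 1.55),
    ("stress", "rt_ms", 0, 0.96),
    ("interaction", "percent_correct", 0, 50.86),
    ("interaction", "percent_correct", 1, 0.62),
    ("interaction", "percent_correct", 2, 0.92),
    ("interaction", "percent_correct", 3, 1.06),
    ("stress_within_young", "percent_correct", 0, 0.71),
    ("stress_within_older", "percent_correct", 1, 1.43),
]


def printed_tolerance(printed: str, abs_floor: float = 0.01, rel: float = 0.01) -> float:
    """Comparison tolerance for a printed value.

    max(absolute floor, relative slack, half a unit of the printed last
    decimal place) — printed values carry rounding of both the displayed
    number and the inputs it was computed from.
    """
    value = abs(float(printed))
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    half_ulp = 0.5 * 10.0 ** (-decimals)
    return max(abs_floor, rel * value, half_ulp)
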