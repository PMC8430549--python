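"""Published per-feature comparison numbers used as test inputs.

The 34 rows of the univariate success-vs-failure comparison, in printed
table order: feature key, group means/SDs, the reported two-sided
rank-sum p-value, the reported rank-indexed threshold (alpha = 0.1,
rounded to 3 decimals) and the printed flag (``**`` significant after
the rank-indexed correction, ``*`` near-significant).
"""

# (feature, success_mean, success_sd, failure_mean, failure_sd, p, alpha_adj, flag)
TABLE2_ROWS = [
    ("hr_sd1", 2.52, 1.45, 2.17, 1.15, 0.316, 0.035, ""),
    ("hr_sd2", 6.74, 4.56, 8.63, 6.98, 0.741, 0.076, ""),
    ("hr_sd1_sd2", 0.43, 0.18, 0.32, 0.13, 0.015, 0.009, "*"),
    ("rr_sd1", 2.76, 1.22, 1.77, 0.49, 0.617, 0.068, ""),
    ("rr_sd2", 2.94, 1.25, 3.08, 1.25, 0.561, 0.059, ""),
    ("rr_sd1_sd2", 0.62, 0.16, 0.65, 0.24, 0.592, 0.065, ""),
    ("vt_sd1", 52.58, 32.96, 27.64, 10.9, 0.237, 0.029, ""),
    ("vt_sd2", 72.90, 40.18, 45.40, 9.86, 0.747, 0.079, ""),
    ("vt_sd1_sd2", 0.72, 0.2, 0.62, 0.19, 0.496, 0.053, ""),
    ("ie_sd1", 61.23, 47.58, 164.57, 297.75, 0.882, 0.094, ""),
    ("ie_sd2", 61.23, 47.58, 189.32, 268.39, 0.408, 0.044, ""),
    ("ie_sd1_sd2", 0.63, 0.22, 0.55, 0.23, 0.318, 0.038, ""),
    ("ti_sd1", 96.20, 68.04, 79.98, 53.70, 0.750, 0.082, ""),
    ("ti_sd2", 146.79, 79.75, 156.47, 117.67, 0.567, 0.062, ""),
    ("ti_sd1_sd2", 0.66, 0.24, 0.58, 0.28, 0.511, 0.056, ""),
    ("map_sd1", 5.37, 4.58, 5.99, 9.42, 0.340, 0.041, ""),
    ("map_sd2", 10.80, 6.09, 15.98, 23.12, 0.832, 0.088, ""),
    ("map_sd1_sd2", 0.5, 0.21, 0.4, 0.17, 0.087, 0.026, ""),
    ("ecg_sampen", 2.04, 0.61, 2.50, 0.46, 0.005, 0.006, "**"),
    ("ecg_alpha1", 1.29, 0.15, 1.22, 0.08, 0.033, 0.021, "*"),
    ("ecg_alpha2", 0.57, 0.23, 0.43, 0.20, 0.016, 0.012, "*"),
    ("ecg_alpha_ratio", 2.83, 2.46, 3.47, 1.57, 0.026, 0.018, "*"),
    ("resp_sampen", 0.21, 0.05, 0.22, 0.05, 0.413, 0.047, ""),
    ("resp_alpha1", 2.03, 0.04, 2.01, 0.03, 0.018, 0.015, "*"),
    ("resp_alpha2", 1.11, 0.27, 1.07, 0.31, 0.719, 0.074, ""),
    ("resp_alpha_ratio", 2.04, 1.11, 2.70, 3.64, 0.973, 0.1, ""),
    ("ppg_sampen", 0.14, 0.05, 0.18, 0.11, 0.002, 0.003, "**"),
    ("ppg_alpha1", 1.96, 0.12, 1.91, 0.19, 0.062, 0.024, ""),
    ("ppg_alpha2", 1.96, 0.12, 0.78, 0.49, 0.429, 0.05, ""),
    ("ppg_alpha_ratio", 5.61, 10.72, -2.15, 29.37, 0.947, 0.097, ""),
    ("abp_sampen", 0.36, 0.39, 0.43, 0.46, 0.247, 0.032, ""),
    ("abp_alpha1", 2.09, 0.01, 2.08, 0.02, 0.627, 0.071, ""),
    ("abp_alpha2", 1.83, 0.10, 1.82, 0.12, 0.775, 0.085, ""),
    ("abp_alpha_ratio", 1.14, 0.07, 1.15, 0.08, 0.853, 0.091, ""),
]

FEATURES = [r[0] for r in TABLE2_ROWS]
PVALUES = [r[5] for r in TABLE2_ROWS]
PRINTED_ALPHA_ADJ = [r[6] for r in TABLE2_ROWS]
SIGNIFICANT = [r[0] for r in TABLE2_ROWS if r[7] == "**"]
NEAR_SIGNIFICANT = [r[0] for r in TABLE2_ROWS if r[7] == "*"]
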