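"""Published summary values used as inputs to significance-rule checks.

These are printed, study-level summary statistics (not patient data): the
FDR-adjusted Fisher p-values reported for co-segregation of six genes with
mutation-positive BRCA1, the corresponding BRCA2 column (reported only as
"not significant"), and the reported anchor-gene prevalences.
"""

from __future__ import annotations

#: FDR-adjusted two-sided Fisher p-values vs mutation-positive BRCA1.
TABLE1_BRCA1_ADJUSTED_P: dict[str, float] = {
    "ERBB2": 0.001,
    "NOTCH1": 0.002,
    "AKT1": 0.011,
    "MTOR": 0.014,
    "ARID1A": 0.008,
    "EGFR": 0.048,
}

#: The BRCA2 column of the same table: every entry reported "NS"
#: (not significant), i.e. adjusted p > 0.05; no numeric value printed.
TABLE1_BRCA2_SIGNIFICANT: dict[str, bool] = {
    gene: False for gene in TABLE1_BRCA1_ADJUSTED_P
}

#: Reported anchor-gene prevalences in the full cohort (fractions).
REPORTED_PREVALENCE = {"BRCA1": 0.046, "BRCA2": 0.0797}

#: Reported cohort sizes: all profiled patients / anchor-mutated patients.
REPORTED_COHORT = {"n_total": 7707, "n_brca_positive": 614}

#: Significance threshold applied throughout (p ≤ alpha).
ALPHA = 0.05


def significant_table1_genes(alpha: float = ALPHA) -> tuple[list[str], list[str]]:
    """Apply the p ≤ alpha rule to the printed adjusted p-values.

    Returns (significant vs BRCA1, significant vs BRCA2).
    """
    brca1 = sorted(g for g, p in TABLE1_BRCA1_ADJUSTED_P.items() if p <= alpha)
    brca2 = sorted(g for g, sig in TABLE1_BRCA2_SIGNIFICANT.items() if sig)
    return brca1, brca2
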