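"""Published significance summary for five forage species × 14 variables.

A published multi-environment analysis of the Finnish official variety
trials (1980–2012, modern cultivars reported for 2000–2012) tabulated,
for every species × agroclimatic variable, the max-diff statistic and
the significance of the G×E interaction and of the environment effect E.
The underlying trial and weather data are not public, but the printed
summary itself is a usable input: it lets the gap-classification logic
be exercised against the analysis' own reported outcome counts.

Each entry is ``(max_diff, gxe, e)`` where ``gxe`` and ``e`` are either
a printed p-value (string of a float) or a star code: ``*`` p ≤ 0.10,
``**`` p ≤ 0.05, ``***`` p ≤ 0.01, ``****`` p ≤ 0.001.  Variable order
follows the printed table; ids are this package's registry ids.
"""

from __future__ import annotations

import pandas as pd

from .gxe import classify_gap

__all__ = [
    "REFERENCE_SIGNIFICANCE",
    "entry_pvalue_bound",
    "significant_gxe_counts",
    "reference_gap_table",
]

REFERENCE_SIGNIFICANCE: dict[str, dict[str, tuple[float, str, str]]] = {
    "timothy": {
        "FH_LENGTH": (-1921, "0.96", "**"),
        "FH_COLD5": (977, "0.90", "0.87"),
        "FH_RAIN": (-1904, "0.86", "*"),
        "WP_WARM0_RATE": (2100, "0.53", "***"),
        "WP_STRESS15": (-1287, "0.25", "****"),
        "GP_TSUM5": (1870, "0.81", "****"),
        "GP_TSUM_RATE": (1702, "0.47", "**"),
        "GP_HOT28": (2756, "0.97", "***"),
        "GP_HOT25_CUT1": (-1503, "0.31", "***"),
        "GP_HOT25_CUT2": (1554, "0.50", "**"),
        "GP_POSTCUT_TSUM7": (-3141, "*", "0.39"),
        "GP_RAIN_CUT1": (-967, "0.63", "0.97"),
        "GP_RAIN_CUT2": (-1609, "0.71", "0.40"),
        "GP_POSTCUT_RAIN14": (-1516, "0.51", "0.74"),
    },
    "meadow_fescue": {
        "FH_LENGTH": (763, "0.65", "0.67"),
        "FH_COLD5": (-1028, "0.62", "***"),
        "FH_RAIN": (1536, "1.00", "***"),
        "WP_WARM0_RATE": (2638, "0.43", "****"),
        "WP_STRESS15": (-2159, "0.29", "****"),
        "GP_TSUM5": (-1067, "0.82", "**"),
        "GP_TSUM_RATE": (-1026, "0.15", "*"),
        "GP_HOT28": (1236, "0.51", "0.42"),
        "GP_HOT25_CUT1": (-1355, "0.14", "0.22"),
        "GP_HOT25_CUT2": (-1354, "**", "**"),
        "GP_POSTCUT_TSUM7": (-1355, "0.97", "**"),
        "GP_RAIN_CUT1": (757, "0.97", "0.65"),
        "GP_RAIN_CUT2": (895, "0.36", "0.27"),
        "GP_POSTCUT_RAIN14": (1229, "0.49", "0.21"),
    },
    "festulolium": {
        "FH_LENGTH": (1006, "**", "0.71"),
        "FH_COLD5": (-1560, "**", "0.11"),
        "FH_RAIN": (2155, "0.21", "****"),
        "WP_WARM0_RATE": (2426, "0.17", "****"),
        "WP_STRESS15": (-1997, "0.15", "****"),
        "GP_TSUM5": (3367, "**", "****"),
        "GP_TSUM_RATE": (579, "0.15", "0.13"),
        "GP_HOT28": (1197, "***", "0.39"),
        "GP_HOT25_CUT1": (946, "**", "***"),
        "GP_HOT25_CUT2": (-831, "***", "0.72"),
        "GP_POSTCUT_TSUM7": (-1770, "0.12", "***"),
        "GP_RAIN_CUT1": (-3049, "****", "***"),
        "GP_RAIN_CUT2": (-1668, "****", "0.68"),
        "GP_POSTCUT_RAIN14": (756, "0.11", "0.32"),
    },
    "tall_fescue": {
        "FH_LENGTH": (1001, "0.24", "0.22"),
        "FH_COLD5": (-1088, "0.80", "**"),
        "FH_RAIN": (1142, "0.74", "**"),
        "WP_WARM0_RATE": (2584, "0.27", "****"),
        "WP_STRESS15": (-1874, "0.31", "****"),
        "GP_TSUM5": (2203, "***", "****"),
        "GP_TSUM_RATE": (589, "0.11", "0.91"),
        "GP_HOT28": (755, "0.04", "0.33"),
        "GP_HOT25_CUT1": (-628, "0.30", "0.23"),
        "GP_HOT25_CUT2": (-533, "0.17", "0.94"),
        "GP_POSTCUT_TSUM7": (-1750, "0.95", "****"),
        "GP_RAIN_CUT1": (291, "0.31", "0.77"),
        "GP_RAIN_CUT2": (-592, "0.39", "0.89"),
        "GP_POSTCUT_RAIN14": (350, "0.94", "0.56"),
    },
    "red_clover": {
        "FH_LENGTH": (1128, "**", "0.64"),
        "FH_COLD5": (1239, "0.37", "0.62"),
        "FH_RAIN": (1011, "0.27", "0.76"),
        "WP_WARM0_RATE": (2114, "*", "***"),
        "WP_STRESS15": (1145, "0.40", "0.21"),
        "GP_TSUM5": (2481, "0.13", "****"),
        "GP_TSUM_RATE": (2747, "0.60", "****"),
        "GP_HOT28": (459, "0.20", "****"),
        "GP_HOT25_CUT1": (877, "0.30", "0.50"),
        "GP_HOT25_CUT2": (2542, "*", "**"),
        "GP_POSTCUT_TSUM7": (-1029, "*", "0.43"),
        "GP_RAIN_CUT1": (655, "0.11", "0.42"),
        "GP_RAIN_CUT2": (1253, "0.26", "0.45"),
        "GP_POSTCUT_RAIN14": (1013, "0.32", "0.16"),
    },
}

_STAR_BOUND = {"*": 0.10, "**": 0.05, "***": 0.01, "****": 0.001}


def entry_pvalue_bound(entry: str) -> float:
    """Upper bound on the p-value behind a printed table entry."""
    if entry in _STAR_BOUND:
        return _STAR_BOUND[entry]
    return float(entry)


def significant_gxe_counts(alpha: float = 0.05) -> dict[str, int]:
    """Per species, how many variables have significant G×E."""
    return {
        sp: sum(
            entry_pvalue_bound(gxe) <= alpha for _, gxe, _ in table.values()
        )
        for sp, table in REFERENCE_SIGNIFICANCE.items()
    }


def reference_gap_table(alpha_e: float = 0.05, alpha_gxe: float = 0.05) -> pd.DataFrame:
    """Apply the gap rule to the published p-values.

    Star codes enter as their upper p bound, so a starred (significant)
    entry stays significant and a bare entry keeps its printed value.
    """
    rows = []
    for sp, table in REFERENCE_SIGNIFICANCE.items():
        for var_id, (md, gxe, e) in table.items():
            p_gxe = entry_pvalue_bound(gxe)
            p_e = entry_pvalue_bound(e)
            gap, rationale = classify_gap(p_e, p_gxe, alpha_e, alpha_gxe)
            rows.append(
                {
                    "species": sp,
                    "variable_id": var_id,
                    "max_diff": md,
                    "p_gxe_bound": p_gxe,
                    "p_e_bound": p_e,
                    "gap": gap,
                    "rationale": rationale,
                }
            )
    return pd.DataFrame(rows)
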