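"""Published reference group summaries for the three treatment arms.

Group-level summary statistics (mean, SD, SEM; n = 16 animals per arm)
for the three endpoints in the spontaneously-hypertensive-rat study the
synthetic generator emulates: mean-arterial-pressure reduction (mmHg),
ultra-early level of edema (ULE) and dose-dependent level of edema (DLE,
per minute).  These are measured in-vivo values: they serve as default
effect sizes for the generator and as inputs to the summary-statistics
ANOVA, not as quantities the pipeline could re-measure.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_SUMMARY", "reference_summary", "GROUP_ORDER", "N_PER_GROUP"]

GROUP_ORDER = ("solvent", "L-CCB", "T&L-CCB")
N_PER_GROUP = 16

#: endpoint -> group -> (mean, sd, sem)
REFERENCE_SUMMARY: dict[str, dict[str, tuple[float, float, float]]] = {
    "map_reduction": {
        "solvent": (2.65, 6.56, 1.64),
        "L-CCB": (68.34, 15.19, 3.80),
        "T&L-CCB": (90.67, 11.58, 2.90),
    },
    "ule": {
        "solvent": (1.16, 0.09, 0.02),
        "L-CCB": (2.08, 0.18, 0.04),
        "T&L-CCB": (1.53, 0.14, 0.04),
    },
    "dle": {
        "solvent": (0.0010, 0.0001, 0.0000),
        "L-CCB": (0.0047, 0.0008, 0.0002),
        "T&L-CCB": (0.0025, 0.0004, 0.0001),
    },
}


def reference_summary() -> pd.DataFrame:
    """Long-form reference table: endpoint, group, n, mean, sd, sem."""
    rows = []
    for endpoint, groups in REFERENCE_SUMMARY.items():
        for group in GROUP_ORDER:
            mean, sd, sem = groups[group]
            rows.append(
                {
                    "endpoint": endpoint,
                    "group": group,
                    "n": N_PER_GROUP,
                    "mean": mean,
                    "sd": sd,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)
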