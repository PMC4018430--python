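"""Spawn-quality classification and phenotype group statistics.

Spawns with more than 50% of eggs bearing viable 4 h embryos are classed
high quality, below 30% low quality, the gap in between intermediate.
Group comparisons use Student's pooled-variance t-test, with proportion
metrics arcsin-square-root transformed first (the standard variance-
stabilizing transform for proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from eggprint.dataio import (
    PHENOTYPE_MORPHOMETRIC_FIELDS,
    PHENOTYPE_PERCENT_FIELDS,
    PhenotypeTable,
)

__all__ = ["classify_spawns", "group_comparison", "arcsin_sqrt", "MetricComparison"]

HIGH_CUTOFF = 50.0  # percent viable 4 h embryos
LOW_CUTOFF = 30.0


def arcsin_sqrt(proportion: np.ndarray) -> np.ndarray:
    """x -> arcsin(sqrt(x)) for x in [0, 1]; strictly monotone, stabilizes
    the variance of binomial proportions."""
    return np.arcsin(np.sqrt(np.asarray(proportion, dtype=float)))


def classify_spawns(pheno: PhenotypeTable) -> PhenotypeTable:
    """Assign quality labels from percent viable 4 h embryos.

    > 50 -> high, < 30 -> low, [30, 50] -> intermediate, missing ->
    unassigned. Total and idempotent on valid tables.
    """
    table = pheno.table.copy()
    pct = table["pct_4h_viable"]
    label = np.select(
        [pct.isna(), pct > HIGH_CUTOFF, pct < LOW_CUTOFF],
        ["unassigned", "high", "low"],
        default="intermediate",
    )
    table["quality_label"] = label
    return PhenotypeTable(table)


@dataclass
class MetricComparison:
    metric: str
    t_statistic: float
    p_value: float
    transformed: bool
    flagged: bool = False  # constant in both groups: p undefined


def group_comparison(pheno: PhenotypeTable) -> list[MetricComparison]:
    """High- vs low-quality two-sided pooled-variance t-tests per metric.

    The four percentage metrics are divided by 100 and arcsin-sqrt
    transformed before testing; morphometrics are tested on their natural
    scale.
    """
    tab = pheno.table
    hi = tab[tab["quality_label"] == "high"]
    lo = tab[tab["quality_label"] == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >= 2 samples per quality group")
    out: list[MetricComparison] = []
    for metric in PHENOTYPE_PERCENT_FIELDS + PHENOTYPE_MORPHOMETRIC_FIELDS:
        if metric not in tab.columns:
            continue
        a = hi[metric].to_numpy(dtype=float)
        b = lo[metric].to_numpy(dtype=float)
        transformed = metric in PHENOTYPE_PERCENT_FIELDS
        if transformed:
            a, b = arcsin_sqrt(a / 100.0), arcsin_sqrt(b / 100.0)
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                out.append(MetricComparison(metric, 0.0, float("nan"),
                                            transformed, flagged=True))
                continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out.append(MetricComparison(metric, float(t), float(p), transformed))
    return out


def comparison_frame(results: list[MetricComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "transformed": [r.transformed for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
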