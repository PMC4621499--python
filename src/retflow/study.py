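"""Two-condition group comparison (room air vs 100% oxygen breathing).

Summaries are means +- SD of per-subject values; note that a group-level
product (e.g. mean flow times mean content difference) does not generally
equal the mean of per-subject products, so both per-subject means and the
group-mean product are surfaced where relevant. Comparisons are two-sided
paired t-tests on subject-matched values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .oxygen_extraction import ExtractionResult
from .units import PERCENT

#: Variable name -> accessor into ExtractionResult. Saturations reported in
#: percent, everything else in its native unit.
_VARIABLES = {
    "q_total_ul_min": lambda r: r.hemodynamics.q_total_ul_min,
    "q_arterial_total_ul_min": lambda r: r.hemodynamics.q_arterial_total_ul_min,
    "q_venous_total_ul_min": lambda r: r.hemodynamics.q_venous_total_ul_min,
    "sat_cra_pct": lambda r: PERCENT * r.oximetry.sat_cra,
    "sat_crv_pct": lambda r: PERCENT * r.oximetry.sat_crv,
    "content_cra_ml_ml": lambda r: r.content_cra_ml_ml,
    "content_crv_ml_ml": lambda r: r.content_crv_ml_ml,
    "content_av_diff_ml_ml": lambda r: r.content_cra_ml_ml - r.content_crv_ml_ml,
    "ext_o2_ul_min": lambda r: r.ext_o2_ul_min,
    "ext_o2_per_100g_ml_min": lambda r: r.ext_o2_per_100g_ml_min,
}


@dataclass(frozen=True)
class GroupComparison:
    """Group summary and paired test for one variable."""

    variable: str
    mean_baseline: float
    sd_baseline: float
    mean_oxygen: float
    sd_oxygen: float
    percent_change: float
    t_statistic: float
    paired_p: float


def paired_t(baseline, oxygen) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p).

    Degenerate difference distributions are resolved explicitly: identical
    pairs give (0, 1); a constant non-zero difference gives (+-inf, 0).
    """
    b = np.asarray(baseline, dtype=float)
    o = np.asarray(oxygen, dtype=float)
    if b.shape != o.shape or b.ndim != 1 or b.size < 2:
        raise ValueError("paired test needs two equal-length 1-D samples, n >= 2")
    d = o - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.isclose(float(d.std(ddof=1)), 0.0):
        return math.copysign(math.inf, float(d.mean())), 0.0
    t, p = stats.ttest_rel(o, b)
    return float(t), float(p)


def compare_conditions(
    results_baseline: list[ExtractionResult],
    results_oxygen: list[ExtractionResult],
) -> list[GroupComparison]:
    """Per-variable group means, SDs, percent change and paired p-values.

    The two lists must cover the same subjects; pairing is by subject_id.
    """
    ids_b = [r.subject_id for r in results_baseline]
    ids_o = [r.subject_id for r in results_oxygen]
    if len(ids_b) != len(ids_o) or set(ids_b) != set(ids_o):
        raise ValueError(
            f"subject mismatch between conditions: {sorted(set(ids_b) ^ set(ids_o))}"
        )
    by_id_o = {r.subject_id: r for r in results_oxygen}
    ordered_b = sorted(results_baseline, key=lambda r: r.subject_id)
    ordered_o = [by_id_o[r.subject_id] for r in ordered_b]
    out = []
    for name, get in _VARIABLES.items():
        vb = np.array([get(r) for r in ordered_b])
        vo = np.array([get(r) for r in ordered_o])
        t, p = paired_t(vb, vo)
        out.append(
            GroupComparison(
                variable=name,
                mean_baseline=float(vb.mean()),
                sd_baseline=float(vb.std(ddof=1)),
                mean_oxygen=float(vo.mean()),
                sd_oxygen=float(vo.std(ddof=1)),
                percent_change=float(
                    PERCENT * (vo.mean() - vb.mean()) / vb.mean()
                ),
                t_statistic=t,
                paired_p=p,
            )
        )
    return out


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Comparisons as a tidy DataFrame (one row per variable)."""
    return pd.DataFrame([vars(c) for c in comparisons]).set_index("variable")


def results_table(results: list[ExtractionResult]) -> pd.DataFrame:
    """Per-subject pipeline outputs as a tidy DataFrame."""
    rows = []
    for r in results:
        row = {"subject_id": r.subject_id, "condition": r.condition.value}
        row.update({name: get(r) for name, get in _VARIABLES.items()})
        row["imbalance_pct"] = PERCENT * r.hemodynamics.imbalance
        row["venous_po2_mmhg"] = r.venous_po2_mmhg
        rows.append(row)
    return pd.DataFrame(rows)
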