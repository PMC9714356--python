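"""Case/control comparison of stratified scans.

The scan is run separately in cases and controls; a pair significant in
either stratum enters the union set and is labeled case_only, control_only
or both. For each implicated CpG the case-vs-control methylation difference
is summarized with a Welch two-sample t-test. Pairs significant in both
strata with opposite effect signs are flagged (``opposite_direction``) — a
pattern of special interest because it would indicate a reversal of the
regulatory direction with disease.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError, MethylationMatrix, SampleTable

CASE_ONLY = "case_only"
CONTROL_ONLY = "control_only"
BOTH = "both"

DIFFERENTIAL_COLUMNS = [
    "snp_id", "cpg_id", "category", "beta_case", "q_case",
    "beta_control", "q_control", "mean_case", "mean_control",
    "mean_diff", "ttest_p", "opposite_direction",
]


class InsufficientDataError(ValueError):
    """A group has fewer than two usable methylation values."""


def cpg_group_ttest(methylation, groups) -> tuple[float, float, float, float]:
    """Welch t-test of one CpG's methylation between cases and controls.

    Returns (mean_case, mean_control, mean_diff, p). mean_diff is
    mean_case - mean_control. If both groups have zero variance the test is
    degenerate: p = 1 when the means agree, else p = 0.
    """
    m = np.asarray(methylation, dtype=float).ravel()
    grp = np.asarray(groups)
    case = m[(grp == "case") & ~np.isnan(m)]
    ctrl = m[(grp == "control") & ~np.isnan(m)]
    if case.size < 2 or ctrl.size < 2:
        raise InsufficientDataError(
            f"need >= 2 values per group, got case={case.size}, "
            f"control={ctrl.size}"
        )
    mean_case, mean_ctrl = float(case.mean()), float(ctrl.mean())
    diff = mean_case - mean_ctrl
    if np.ptp(case) == 0.0 and np.ptp(ctrl) == 0.0:
        return mean_case, mean_ctrl, diff, 1.0 if diff == 0.0 else 0.0
    p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    return mean_case, mean_ctrl, diff, p


def categorize(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label each pair significant in either stratum by where it was found.

    Both inputs must come from scans over the same SNP-CpG universe (same
    pair set); significance means per-SNP q < alpha within each stratum
    independently. Output is sorted by (snp_id, cpg_id).
    """
    key = ["snp_id", "cpg_id"]
    case_idx = case_records.set_index(key)
    ctrl_idx = control_records.set_index(key)
    if set(case_idx.index) != set(ctrl_idx.index):
        raise DataError(
            "case and control scans cover different SNP-CpG universes"
        )
    sig_case = case_idx.index[case_idx["q_value"] < alpha]
    sig_ctrl = ctrl_idx.index[ctrl_idx["q_value"] < alpha]
    union = sig_case.union(sig_ctrl).sort_values()

    rows = []
    for pair in union:
        in_case = pair in sig_case
        in_ctrl = pair in sig_ctrl
        category = BOTH if (in_case and in_ctrl) else (
            CASE_ONLY if in_case else CONTROL_ONLY
        )
        b_case = case_idx.loc[pair, "beta_hat"]
        b_ctrl = ctrl_idx.loc[pair, "beta_hat"]
        opposite = bool(
            category == BOTH
            and np.isfinite(b_case) and np.isfinite(b_ctrl)
            and np.sign(b_case) * np.sign(b_ctrl) < 0
        )
        rows.append(
            {
                "snp_id": pair[0],
                "cpg_id": pair[1],
                "category": category,
                "beta_case": b_case,
                "q_case": case_idx.loc[pair, "q_value"],
                "beta_control": b_ctrl,
                "q_control": ctrl_idx.loc[pair, "q_value"],
                "opposite_direction": opposite,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "cpg_id", "category", "beta_case", "q_case",
                 "beta_control", "q_control", "opposite_direction"],
    )


def compare(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    methylation: MethylationMatrix,
    samples: SampleTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full differential table: categories plus Welch t-test per CpG."""
    calls = categorize(case_records, control_records, alpha)
    groups = samples.table.loc[methylation.sample_ids, "group"].to_numpy()

    means_case = np.full(len(calls), np.nan)
    means_ctrl = np.full(len(calls), np.nan)
    diffs = np.full(len(calls), np.nan)
    pvals = np.full(len(calls), np.nan)
    for i, cpg_id in enumerate(calls["cpg_id"]):
        m = methylation.values.loc[cpg_id].to_numpy(dtype=float)
        means_case[i], means_ctrl[i], diffs[i], pvals[i] = cpg_group_ttest(
            m, groups
        )
    calls["mean_case"] = means_case
    calls["mean_control"] = means_ctrl
    calls["mean_diff"] = diffs
    calls["ttest_p"] = pvals
    return calls[DIFFERENTIAL_COLUMNS]
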