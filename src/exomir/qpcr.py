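"""qPCR delta-CT relative quantification against a reference miRNA.

Each well records a cycle-threshold (CT); lower CT means more template.
Within every plate, replicate CTs are averaged per (sample, target) and
the reference target's average CT on the same plate is subtracted,
cancelling plate-to-plate calibration offsets.  Per-plate delta-CTs are
then averaged (unweighted) into one delta-CT per sample and target.
Group contrasts use a two-sample t-test on the sample delta-CTs and the
fold change follows the standard relation

    fold = 2 ** (-ddCT),   ddCT = mean dCT(case) - mean dCT(control),

so one cycle earlier in cases (ddCT = -1) means a two-fold increase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["read_wells", "plate_delta_ct", "group_compare", "fold_change",
           "QpcrResult", "results_table"]

WELL_COLUMNS = ["sample", "target", "plate", "replicate", "ct"]


def read_wells(path) -> pd.DataFrame:
    """Read a long-format well table CSV (sample,target,plate,replicate,ct)."""
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("non-finite CT values in well table")
    return df


def plate_delta_ct(wells: pd.DataFrame, reference_target: str) -> pd.DataFrame:
    """Per-sample delta-CT records.

    Replicates are averaged within (sample, target, plate); the reference
    average on the same (sample, plate) is subtracted; per-plate delta-CTs
    are averaged unweighted across plates.  Plates lacking the reference
    for a sample are dropped with a warning; a sample whose target
    measurements have no co-measured reference on any plate is an error.

    Returns columns: sample, target, delta_ct, n_plates.
    """
    means = (wells.groupby(["sample", "target", "plate"], sort=False)["ct"]
             .mean().reset_index())
    ref = means[means["target"] == reference_target]
    if ref.empty:
        raise ValueError(f"reference target {reference_target!r} absent "
                         "from well table")
    ref_lookup = ref.set_index(["sample", "plate"])["ct"]
    records = []
    targets = means[means["target"] != reference_target]
    for (sample, target), grp in targets.groupby(["sample", "target"],
                                                 sort=False):
        deltas = []
        for _, row in grp.iterrows():
            key = (sample, row["plate"])
            if key in ref_lookup.index:
                deltas.append(row["ct"] - ref_lookup[key])
            else:
                logger.warning("plate %s lacks reference for sample %s; "
                               "dropped", row["plate"], sample)
        if not deltas:
            raise ValueError(f"no plate carries reference "
                             f"{reference_target!r} for sample {sample!r}")
        records.append({"sample": sample, "target": target,
                        "delta_ct": float(np.mean(deltas)),
                        "n_plates": len(deltas)})
    return pd.DataFrame(records)


def fold_change(delta_delta_ct: float) -> float:
    """Relative expression 2**(-ddCT); strictly decreasing in ddCT and
    multiplicative over sums: fold(a+b) = fold(a)*fold(b)."""
    return float(2.0 ** (-np.asarray(delta_delta_ct, dtype=float)))


@dataclass
class QpcrResult:
    target: str
    group_case: str
    group_control: str
    mean_dct_case: float
    mean_dct_control: float
    n_case: int
    n_control: int
    p_value: float
    fold: float


def group_compare(records: pd.DataFrame, samples: pd.DataFrame, target: str,
                  g_case: str, g_control: str,
                  equal_var: bool = True) -> QpcrResult:
    """Two-sided two-sample t-test on sample delta-CTs for one target,
    case group vs control group, with the 2**(-ddCT) fold change.

    ``equal_var=True`` gives the classical Student's test; set False for
    Welch.
    """
    meta = samples.set_index("sample")["group"]
    sub = records[records["target"] == target].copy()
    sub["group"] = sub["sample"].map(meta)
    case = sub.loc[sub["group"] == g_case, "delta_ct"].to_numpy()
    control = sub.loc[sub["group"] == g_control, "delta_ct"].to_numpy()
    if len(case) < 2 or len(control) < 2:
        raise ValueError(f"need >= 2 delta-CT records per group for "
                         f"{target!r} ({g_case}: {len(case)}, "
                         f"{g_control}: {len(control)})")
    tt = stats.ttest_ind(case, control, equal_var=equal_var)
    ddct = float(case.mean() - control.mean())
    return QpcrResult(target=target, group_case=g_case,
                      group_control=g_control,
                      mean_dct_case=float(case.mean()),
                      mean_dct_control=float(control.mean()),
                      n_case=len(case), n_control=len(control),
                      p_value=float(tt.pvalue), fold=fold_change(ddct))


def results_table(results_by_contrast: dict, alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Summary in the published layout: one row per target, a p-value
    column per contrast and the fold change shown only where p < alpha.

    ``results_by_contrast`` maps a contrast label (e.g. "BD") to a list of
    :class:`QpcrResult`.
    """
    targets = []
    for results in results_by_contrast.values():
        for r in results:
            if r.target not in targets:
                targets.append(r.target)
    rows = {t: {"miRNA": t} for t in targets}
    for label, results in results_by_contrast.items():
        for r in results:
            rows[r.target][f"p-value, {label}"] = r.p_value
            rows[r.target][f"Significant fold change, {label}"] = (
                round(r.fold, 2) if r.p_value < alpha else "")
    return pd.DataFrame(list(rows.values()))
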