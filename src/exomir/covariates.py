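"""Medication-class covariate adjustment of disease z-scores.

Prescribed medications confound case-control contrasts in postmortem
psychiatric cohorts.  The procedure implemented here quantifies each drug
class's influence as a two-group standardized score — case subjects taking
at least one drug of the class versus case subjects not taking any — and
subtracts that effect from the disease z-score of each miRNA.  A drug
class is only evaluable when both the taker and non-taker side have at
least three case subjects (a standard error must be estimable on each
side); eligibility is assessed within the diagnostic groups in which the
class is actually used, since a class prescribed to one diagnosis only
(e.g. mood stabilizers in bipolar disorder) cannot borrow non-takers from
the other diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sam import GroupDesign, group_zscores, compute_s0

logger = logging.getLogger(__name__)

__all__ = ["DrugClassDesign", "eligible_classes", "covariate_effect",
           "adjust_scores", "adjusted_pvalue"]

CONTROL_GROUP = "C"
DRUG_CLASSES = tuple("ABCDEFG")


@dataclass
class DrugClassDesign:
    """Taker / non-taker partitions of the case subjects per drug class."""
    takers: dict       # class letter -> sorted list of sample ids
    non_takers: dict   # class letter -> sorted list of sample ids
    eligible: dict     # class letter -> bool
    scope_groups: dict  # class letter -> groups in which the class is used

    def eligible_letters(self) -> list:
        return [c for c in self.takers if self.eligible[c]]


def eligible_classes(samples: pd.DataFrame, cohort=None,
                     classes=DRUG_CLASSES,
                     min_per_side: int = 3) -> DrugClassDesign:
    """Partition case subjects into takers and non-takers per drug class
    and flag the classes evaluable as covariates.

    ``cohort`` restricts to the sample ids actually analyzed (default: all
    rows of ``samples``).  Controls are excluded: they take none of the
    listed medication classes.  Non-takers are counted within the
    diagnostic groups that contain at least one taker of the class.
    """
    meta = samples.set_index("sample")
    if cohort is None:
        cohort = list(meta.index)
    else:
        cohort = list(cohort)
        missing = [s for s in cohort if s not in meta.index]
        if missing:
            raise ValueError(f"cohort samples missing from metadata: {missing}")
    takers, non_takers, eligible, scope = {}, {}, {}, {}
    for cls in classes:
        col = f"class{cls}"
        if col not in meta.columns:
            raise ValueError(f"unknown drug class {cls!r}")
        cases = [s for s in cohort if meta.at[s, "group"] != CONTROL_GROUP]
        t = sorted(s for s in cases if bool(meta.at[s, col]))
        groups_used = sorted({meta.at[s, "group"] for s in t})
        in_scope = [s for s in cases if meta.at[s, "group"] in groups_used]
        nt = sorted(s for s in in_scope if s not in t)
        takers[cls], non_takers[cls] = t, nt
        scope[cls] = groups_used
        eligible[cls] = len(t) >= min_per_side and len(nt) >= min_per_side
    return DrugClassDesign(takers=takers, non_takers=non_takers,
                           eligible=eligible, scope_groups=scope)


def covariate_effect(m: pd.DataFrame, design: DrugClassDesign, class_id: str,
                     s0: float | None = None) -> pd.Series:
    """Per-miRNA covariate-effect score for one drug class: the taker-group
    standardized score of the two-group (taker vs non-taker) contrast,
    using the same s0 convention as the disease analysis."""
    if class_id not in design.takers:
        raise ValueError(f"unknown drug class {class_id!r}")
    if not design.eligible[class_id]:
        raise ValueError(f"drug class {class_id!r} is not eligible "
                         "(needs >= 3 takers and >= 3 non-takers)")
    t, nt = design.takers[class_id], design.non_takers[class_id]
    cols = t + nt
    X = m[cols].to_numpy(dtype=float)
    labels = np.array(["taker"] * len(t) + ["non_taker"] * len(nt))
    gd = GroupDesign.from_labels(labels)
    if s0 is None:
        s0 = compute_s0(X, gd)
    z = group_zscores(X, gd, s0)
    return pd.Series(z["taker"].to_numpy(), index=m.index, name=class_id)


def adjust_scores(z, effects: pd.DataFrame, classes) -> pd.Series:
    """Adjusted score z - sum of the requested class effects, per miRNA.

    ``effects`` has one column per class letter (NaN/missing cells mean no
    effect was computed and contribute zero, logged).  Exact arithmetic:
    an empty class set is the identity.
    """
    z = pd.Series(z, dtype=float)
    adjusted = z.copy()
    for cls in classes:
        if cls not in effects.columns:
            logger.warning("no effects for class %s; treated as 0", cls)
            continue
        e = effects[cls].reindex(z.index)
        n_missing = int(e.isna().sum())
        if n_missing:
            logger.info("class %s: %d missing effects treated as 0",
                        cls, n_missing)
        adjusted = adjusted - e.fillna(0.0)
    return adjusted


def adjusted_pvalue(z_adj: float, null_scores: np.ndarray) -> float:
    """Two-sided permutation tail probability of |z_adj| with add-one
    smoothing: p = (1 + #{|null| >= |z_adj|}) / (B + 1), so p >= 1/(B+1)
    and a centered score gives p = 1 within smoothing."""
    null_scores = np.abs(np.asarray(null_scores, dtype=float).ravel())
    B = null_scores.size
    count = int((null_scores >= abs(z_adj)).sum())
    return (1 + count) / (B + 1)
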