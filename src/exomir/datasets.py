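"""Packaged reference tables for the three-group prefrontal-cortex
exosomal miRNA cohort (6 controls, 6 bipolar disorder, 8 schizophrenia).

These small TSV files transcribe the published summary tables of the study
cohort — the ranked score tables of the three-group and BD-vs-control
analyses, the medication-class covariate effects and adjusted scores, the
per-case medication flags, and the qPCR t-test summary.  They serve as
worked-arithmetic fixtures: the raw expression matrix itself was never
deposited, but the internal consistency of these tables (weighted z-score
identity, effect-subtraction arithmetic, zero-q counts) is fully checkable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_sam_scores_three_group",
    "load_sam_scores_bd_vs_control",
    "load_covariate_effects",
    "load_adjusted_scores_sz",
    "load_adjusted_scores_bd",
    "load_medications",
    "load_qpcr_ttests",
    "load_study_metadata",
]

GROUP_SIZES = {"C": 6, "BD": 6, "SZ": 8}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("exomir.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_sam_scores_three_group() -> pd.DataFrame:
    """198 miRNAs ranked by the three-group standardized scores, with
    per-group z-scores, q-value (%) and local FDR (%)."""
    return _read("sam_scores_three_group.tsv")


def load_sam_scores_bd_vs_control() -> pd.DataFrame:
    """Top of the BD-vs-control ranking: q-value (%) and local FDR (%)."""
    return _read("sam_scores_bd_vs_control.tsv")


def load_covariate_effects() -> pd.DataFrame:
    """Medication-class (A, B, C) covariate-effect scores for the
    highly ranked miRNAs; blank cells mean no effect was computed."""
    return _read("covariate_effects.tsv")


def load_adjusted_scores_sz() -> pd.DataFrame:
    """Covariate-adjusted SZ scores (classes A, B, C, B+C) with p-values."""
    return _read("adjusted_scores_sz.tsv")


def load_adjusted_scores_bd() -> pd.DataFrame:
    """Covariate-adjusted BD scores.  Transcribed verbatim; the later rows
    of the published table interleave columns inconsistently, so this
    fixture is for inspection rather than arithmetic checks."""
    return _read("adjusted_scores_bd.tsv")


def load_medications() -> pd.DataFrame:
    """Per-case medication-class flags A-G (1/0) for the SZ and BD cases;
    controls take none of the listed classes."""
    return _read("medications.tsv")


def load_qpcr_ttests() -> pd.DataFrame:
    """qPCR delta-CT t-test summary: per target, p-values for the BD and SZ
    contrasts and the significant fold changes (2.77 for miR-29c in BD,
    2.35 for miR-497 in SZ)."""
    return _read("qpcr_ttests.tsv")


def load_study_metadata() -> pd.DataFrame:
    """Sample table for the 20-sample array cohort (C1-6, BD1-6, SZ1-8):
    group label and the seven medication-class flags.  Age and sex are not
    part of the packaged flags table and are filled with NA."""
    meds = load_medications().set_index("sample")
    rows = []
    for g, n in GROUP_SIZES.items():
        for i in range(1, n + 1):
            sid = f"{g}{i}"
            flags = {f"class{c}": bool(meds.at[sid, c]) if sid in meds.index
                     else False for c in "ABCDEFG"}
            rows.append({"sample": sid, "group": g, **flags,
                         "age": pd.NA, "sex": pd.NA})
    return pd.DataFrame(rows)
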