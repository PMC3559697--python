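"""Synthetic cohort generator for the exosomal miRNA analysis pipeline.

The raw expression data behind the three-group prefrontal-cortex cohort
(6 controls, 6 bipolar-disorder and 8 schizophrenia samples, 312 miRNAs
assayed per sample on a multiplexed bead array) was never deposited, so
downstream stages are exercised on simulated matrices with the same
statistical structure:

* a log-normal baseline per miRNA (log2-scale abundance ~ N(mu, sigma)),
* an additive log2-scale group effect for a spiked differentially
  expressed subset,
* additive log2-scale medication-class effects for takers of a drug class,
* Gaussian within-group noise on the log2 scale,
* raw readings emitted after subtracting a background constant, so
  below-background values appear as negatives exactly as the instrument
  reports them (the preprocessing floor stage then maps them to 0).

A machine-readable truth table accompanies every matrix so recovery can
be scored without peeking at the generator internals.

A single seed governs everything; sub-generators (metadata, qPCR wells)
use fixed offsets from it, so a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .datasets import load_medications

__all__ = ["SimConfig", "SimTruth", "simulate_expression",
           "simulate_metadata", "simulate_qpcr", "write_truth", "read_truth"]

DEFAULT_GROUP_SIZES = {"C": 6, "BD": 6, "SZ": 8}


def _default_covariate_assignment() -> dict:
    """Medication-class assignment of the array cohort (case samples only;
    controls take none of the listed drug classes)."""
    meds = load_medications()
    cohort = [f"SZ{i}" for i in range(1, 9)] + [f"BD{i}" for i in range(1, 7)]
    meds = meds[meds["sample"].isin(cohort)]
    out = {}
    for cls in "ABCDEFG":
        out[cls] = set(meds.loc[meds[cls] == 1, "sample"])
    return out


@dataclass
class SimConfig:
    """Generator configuration.  Defaults reproduce the study design:
    312 miRNAs, groups C:6 / BD:6 / SZ:8, differentially expressed subsets
    roughly matching the 21 three-group and 7 two-group zero-q calls, and
    the published medication-class assignment."""
    n_mirnas: int = 312
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_spiked_per_group: dict = field(
        default_factory=lambda: {"SZ": 14, "BD": 7})
    effect_size_log2: float = 2.0
    baseline_log_mean_sd: tuple = (6.0, 2.0)
    noise_sd: float = 0.5
    background_threshold: float = 30.0
    covariate_assignment: dict = field(
        default_factory=_default_covariate_assignment)
    covariate_effect_log2: float = 0.0
    n_covariate_affected: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_mirnas <= 0:
            raise ValueError("n_mirnas must be positive")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} size must be positive")
        for g, n in self.n_spiked_per_group.items():
            if n < 0 or n > self.n_mirnas:
                raise ValueError(
                    f"n_spiked for group {g!r} outside [0, n_mirnas]")
            if g not in self.group_sizes:
                raise ValueError(f"spiked group {g!r} not in group_sizes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def sample_ids(self) -> list:
        return [f"{g}{i + 1}" for g, n in self.group_sizes.items()
                for i in range(n)]

    @property
    def sample_groups(self) -> list:
        return [g for g, n in self.group_sizes.items() for _ in range(n)]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariate_assignment" in raw:
            raw["covariate_assignment"] = {
                k: set(v) for k, v in raw["covariate_assignment"].items()}
        if "baseline_log_mean_sd" in raw:
            raw["baseline_log_mean_sd"] = tuple(raw["baseline_log_mean_sd"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["covariate_assignment"] = {
            k: sorted(v) for k, v in self.covariate_assignment.items()}
        raw["baseline_log_mean_sd"] = list(self.baseline_log_mean_sd)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth: which miRNAs carry a group effect (and where), and
    which carry medication-class effects."""
    spiked_mirnas: dict      # miRNA id -> (group, log2 effect)
    covariate_affected: dict  # miRNA id -> set of class letters


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "spiked_mirnas": {k: [v[0], v[1]] for k, v in
                          truth.spiked_mirnas.items()},
        "covariate_affected": {k: sorted(v) for k, v in
                               truth.covariate_affected.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        spiked_mirnas={k: (v[0], float(v[1])) for k, v in
                       payload["spiked_mirnas"].items()},
        covariate_affected={k: set(v) for k, v in
                            payload["covariate_affected"].items()},
    )


def _mirna_ids(n: int) -> list:
    return [f"sim-miR-{i + 1:04d}" for i in range(n)]


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a raw expression matrix (miRNAs x samples, possibly negative)
    and its truth table.

    Raw reading = 2**(log2 signal) - background_threshold, so weakly
    expressed miRNAs fall below zero, exercising the flooring stage.
    """
    rng = np.random.default_rng(config.seed)
    ids = _mirna_ids(config.n_mirnas)
    samples = config.sample_ids
    groups = np.array(config.sample_groups)
    m, n = config.n_mirnas, len(samples)

    mu, sd = config.baseline_log_mean_sd
    baseline = rng.normal(mu, sd, size=m)
    log2_signal = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(m, n))

    # spiked subsets: disjoint across groups, drawn without replacement
    spiked: dict = {}
    available = list(range(m))
    for g, k in config.n_spiked_per_group.items():
        chosen = rng.choice(len(available), size=k, replace=False)
        rows = [available[c] for c in sorted(chosen, reverse=True)]
        for r in rows:
            available.remove(r)
        for r in rows:
            spiked[ids[r]] = (g, config.effect_size_log2)
            log2_signal[r, groups == g] += config.effect_size_log2

    # medication-class effects: additive on log2 scale in takers only
    covariate_affected: dict = {}
    if config.n_covariate_affected > 0 and config.covariate_effect_log2 != 0:
        active = [c for c, members in config.covariate_assignment.items()
                  if members]
        for cls in active:
            chosen = rng.choice(len(available),
                                size=min(config.n_covariate_affected,
                                         len(available)),
                                replace=False)
            rows = [available[c] for c in sorted(chosen, reverse=True)]
            for r in rows:
                available.remove(r)
            takers = [j for j, sid in enumerate(samples)
                      if sid in config.covariate_assignment[cls]]
            for r in rows:
                covariate_affected.setdefault(ids[r], set()).add(cls)
                log2_signal[r, takers] += config.covariate_effect_log2

    raw = 2.0 ** log2_signal - config.background_threshold
    df = pd.DataFrame(raw, index=pd.Index(ids, name="mirna"),
                      columns=samples)
    return df, SimTruth(spiked_mirnas=spiked,
                        covariate_affected=covariate_affected)


def simulate_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample table: group, seven medication-class flags A-G (all False
    for controls), age and sex.  Sex skews male, mirroring the cohort."""
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for sid, g in zip(config.sample_ids, config.sample_groups):
        flags = {f"class{c}": (g != "C" and
                               sid in config.covariate_assignment.get(c, ()))
                 for c in "ABCDEFG"}
        rows.append({
            "sample": sid, "group": g, **flags,
            "age": int(np.clip(round(rng.normal(60, 12)), 25, 95)),
            "sex": "M" if rng.random() < 0.85 else "F",
        })
    return pd.DataFrame(rows)


def simulate_qpcr(config: SimConfig, expression: pd.DataFrame,
                  targets: list, n_plates: int = 3, n_replicates: int = 2,
                  reference_target: str | None = None,
                  intercept: float = 36.0, slope: float = 1.0,
                  noise_sd: float = 0.25,
                  plate_offset_sd: float = 0.5) -> pd.DataFrame:
    """Long-format qPCR well table (sample, target, plate, replicate, ct).

    CT = intercept - slope * log2(expression + 1) + plate offset + noise.
    The reference target is simulated from its mean expression across
    samples, so its CT is constant across samples up to noise — the
    behavior a good reference gene must have.  Per-plate offsets emulate
    inter-plate calibration shifts; they cancel in delta-CT.
    """
    if n_plates < 1 or n_replicates < 1:
        raise ValueError("n_plates and n_replicates must be >= 1")
    all_targets = list(targets)
    if reference_target is not None and reference_target not in all_targets:
        all_targets.append(reference_target)
    for t in all_targets:
        if t not in expression.index:
            raise KeyError(f"target {t!r} not in expression matrix")
    rng = np.random.default_rng(config.seed + 2)
    plate_offsets = rng.normal(0.0, plate_offset_sd, size=n_plates)
    rows = []
    for plate in range(1, n_plates + 1):
        for target in all_targets:
            expr_row = expression.loc[target]
            if target == reference_target:
                expr_row = pd.Series(float(np.clip(expr_row.mean(), 0, None)),
                                     index=expr_row.index)
            for sample in expression.columns:
                base_ct = intercept - slope * np.log2(
                    max(float(expr_row[sample]), 0.0) + 1.0)
                for rep in range(1, n_replicates + 1):
                    ct = base_ct + plate_offsets[plate - 1] + \
                        rng.normal(0.0, noise_sd)
                    rows.append({"sample": sample, "target": target,
                                 "plate": plate, "replicate": rep,
                                 "ct": ct})
    return pd.DataFrame(rows)
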