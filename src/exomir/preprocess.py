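"""Reading, writing and preprocessing of bead-array miRNA expression matrices.

The expression matrix convention throughout this package is miRNAs in rows
and samples in columns (a pandas DataFrame with miRNA ids as index and
sample ids as columns).  Raw bead-array readings can be negative — the
instrument reports values below background as negatives — and the first
preprocessing step floors them to zero.  Subsequent steps remove
uninformative rows, put samples on a common scale, and (for clustering)
apply a cube-root variance-stabilizing transform.

scikit-learn-compatible transformer classes are provided for use inside
pipelines; they follow the sklearn convention of samples in rows, so they
operate on the transpose of the DataFrame layout above.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "floor_negatives",
    "filter_informative",
    "normalize_samples",
    "cube_root",
    "NegativeFloor",
    "MedianScaleNormalizer",
    "CubeRootTransformer",
]

METADATA_COLUMNS = ["sample", "group", "classA", "classB", "classC",
                    "classD", "classE", "classF", "classG", "age", "sex"]


class ExpressionFormatError(ValueError):
    """Raised when an expression table violates the declared format."""


def read_expression(path) -> pd.DataFrame:
    """Read a tab-separated expression table (first column: miRNA id,
    remaining columns: sample ids).

    Negative entries are allowed at this stage; they are handled by
    :func:`floor_negatives`.

    Raises
    ------
    ExpressionFormatError
        On duplicate miRNA ids or non-numeric cells (reported with the
        offending row and column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionFormatError(f"duplicate miRNA ids: {dups}")
    if df.columns.duplicated().any():
        raise ExpressionFormatError("duplicate sample ids in header")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ExpressionFormatError(
                f"non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        values[col] = converted
    return values


def write_expression(m: pd.DataFrame, path) -> None:
    """Write an expression matrix in the TSV dialect of :func:`read_expression`."""
    m.to_csv(path, sep="\t", index_label="mirna")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV (sample, group, classA..classG, age, sex)."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionFormatError(f"metadata missing columns: {missing}")
    for c in METADATA_COLUMNS[2:9]:
        df[c] = df[c].astype(bool)
    return df


def write_metadata(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    for c in METADATA_COLUMNS[2:9]:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def floor_negatives(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace below-background (negative) readings with 0.

    Negative raw values indicate expression below the assay background and
    carry no abundance information, so they are floored to zero.

    Returns
    -------
    floored : DataFrame
        Matrix with every negative entry replaced by 0.
    flags : DataFrame of bool
        Provenance mask, True where an entry was floored.
    """
    flags = raw < 0
    floored = raw.where(~flags, 0.0)
    return floored, flags


def filter_informative(m: pd.DataFrame, min_expressed_samples: int = 3) -> pd.DataFrame:
    """Retain miRNAs expressed (> 0) in at least ``min_expressed_samples``
    samples and with nonzero variance across samples.

    Row order is preserved; the number of removed rows is logged.
    """
    n_samples = m.shape[1]
    if not 1 <= min_expressed_samples <= n_samples:
        raise ValueError(
            f"min_expressed_samples={min_expressed_samples} outside "
            f"[1, {n_samples}]"
        )
    expressed = (m > 0).sum(axis=1) >= min_expressed_samples
    informative = m.var(axis=1, ddof=0) > 0
    keep = expressed & informative
    removed = int((~keep).sum())
    logger.info("filter_informative: removed %d of %d miRNAs", removed, len(m))
    return m.loc[keep]


def normalize_samples(m: pd.DataFrame,
                      target_median: float | None = None) -> pd.DataFrame:
    """Scale each sample (column) so its median positive value equals a
    common target — by default the global median of per-column median
    positives, or a fixed ``target_median``.

    Zeros encode "below background", not abundance, so they are excluded
    from the scaling statistic and stay exactly zero.  Columns that are
    scalar multiples of one another become identical, and the operation is
    idempotent up to floating-point rounding.  With a fixed target the
    result is exactly invariant to rescaling any single column; with the
    data-driven target the invariance holds up to one global factor
    (the target itself moves with the column medians).
    """
    col_medians = {}
    for col in m.columns:
        pos = m[col][m[col] > 0]
        if pos.empty:
            raise ValueError(f"sample {col!r} has no positive values; "
                             "cannot normalize an all-zero column")
        col_medians[col] = float(pos.median())
    target = float(np.median(list(col_medians.values()))) \
        if target_median is None else float(target_median)
    scaled = m.copy()
    for col in m.columns:
        scaled[col] = m[col] * (target / col_medians[col])
    return scaled


def cube_root(m: pd.DataFrame | np.ndarray):
    """Entrywise cube root (the variance-stabilizing transform used for
    sample clustering).  Monotone; 0 maps to 0."""
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(np.cbrt(m.to_numpy()), index=m.index,
                            columns=m.columns)
    return np.cbrt(np.asarray(m, dtype=float))


# --------------------------------------------------------------------------
# sklearn transformer wrappers (samples in rows, features in columns)

class NegativeFloor(TransformerMixin, BaseEstimator):
    """Floor below-background (negative) readings to zero.

    Stateless; ``fit`` only validates input.  After ``transform`` the
    attribute ``n_floored_`` holds the number of entries floored in the most
    recent call.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        mask = X < 0
        self.n_floored_ = int(mask.sum())
        return np.where(mask, 0.0, X)


class MedianScaleNormalizer(TransformerMixin, BaseEstimator):
    """Per-sample median-of-positives scaling (see :func:`normalize_samples`).

    The target median is learned at ``fit`` time from the fitted data so
    the transform is well-defined for new samples.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        medians = self._row_medians(X)
        self.target_median_ = float(np.median(medians))
        return self

    @staticmethod
    def _row_medians(X):
        medians = np.empty(X.shape[0])
        for i, row in enumerate(X):
            pos = row[row > 0]
            if pos.size == 0:
                raise ValueError(f"sample at row {i} has no positive values")
            medians[i] = np.median(pos)
        return medians

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        medians = self._row_medians(X)
        return X * (self.target_median_ / medians)[:, None]


class CubeRootTransformer(TransformerMixin, BaseEstimator):
    """Entrywise cube-root transform."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return np.cbrt(check_array(X))
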