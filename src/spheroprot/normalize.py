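"""Normalization cascade and QC statistics.

Stage order: ``replace_zeros -> median_normalize -> log2_transform ->
reference_scale -> center_rows``.  The cascade is deterministic and
removes any whole-batch multiplicative factor (per-batch reference
subtraction) as well as per-channel loading differences (median
normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spheroprot.design import StudyDesign
from spheroprot.quant import LogMatrix, QuantMatrix

DEFAULT_ZERO_FLOOR = 0.1


def replace_zeros(q: QuantMatrix, floor: float = DEFAULT_ZERO_FLOOR) -> QuantMatrix:
    """Replace every literal 0 with ``floor``; NAs are untouched."""
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    values = q.values.mask(q.values == 0, floor)
    return q.with_values(values)


def median_normalize(q: QuantMatrix) -> QuantMatrix:
    """Equalize channel medians, rescaling to the grand median.

    Each channel is divided by its own median (over finite values) and
    multiplied by the median of all channel medians, so values stay on an
    interpretable S/N-like scale.
    """
    medians = q.values.median(axis=0, skipna=True)
    if (medians <= 0).any() or medians.isna().any():
        bad = medians.index[(medians <= 0) | medians.isna()].tolist()
        raise ValueError(f"nonpositive or undefined channel median: {bad[:5]}")
    grand = float(medians.median())
    values = q.values / medians * grand
    return q.with_values(values)


def log2_transform(q: QuantMatrix) -> LogMatrix:
    """Elementwise log2; NAs propagate; nonpositive values are an error."""
    if (q.values <= 0).any().any():
        raise ValueError("nonpositive values present; run replace_zeros first")
    return LogMatrix(values=np.log2(q.values), design=q.design.copy(), stage="raw-log2")


def reference_scale(m: LogMatrix, design: StudyDesign | None = None) -> LogMatrix:
    """Subtract, per batch, each protein's mean over that batch's references.

    Reference channels are scaled too, so reference replicates become
    directly comparable across batches (the batch-effect QC).
    """
    values = m.values.copy()
    for b in m.batches:
        ref_keys = m.batch_reference_keys(b)
        if not ref_keys:
            raise ValueError(f"batch {b} has no reference channels")
        ref_mean = m.values[ref_keys].mean(axis=1, skipna=True)
        batch_keys = m.batch_keys(b)
        values[batch_keys] = m.values[batch_keys].sub(ref_mean, axis=0)
    return LogMatrix(values=values, design=m.design.copy(), stage="reference-scaled")


def center_rows(m: LogMatrix) -> LogMatrix:
    """Subtract each protein's mean over the biological sample channels.

    The row mean is computed over finite sample-channel entries only and
    subtracted from every channel (references included), so sample rows
    end centered at zero and references stay on the same scale.
    """
    row_mean = m.values[m.sample_keys].mean(axis=1, skipna=True)
    values = m.values.sub(row_mean, axis=0)
    return LogMatrix(values=values, design=m.design.copy(), stage="centered")


def normalize_pipeline(
    q: QuantMatrix, floor: float = DEFAULT_ZERO_FLOOR
) -> LogMatrix:
    """Full cascade from raw nonnegative values to the centered log matrix."""
    return center_rows(reference_scale(log2_transform(median_normalize(replace_zeros(q, floor)))))


# ---------------------------------------------------------------------------
# QC statistics


@dataclass
class PcaResult:
    """Per-sample component scores and explained-variance fractions."""

    scores: pd.DataFrame  # channels x components
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(np.diff(vf) > 1e-12) or vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be nonincreasing and sum to <= 1")


def run_pca(m: LogMatrix, k: int = 2, include_references: bool = True) -> PcaResult:
    """SVD-based PCA of channels over the row-mean-subtracted matrix.

    Proteins with any missing value across the used channels are dropped
    before decomposition.
    """
    keys = m.channel_keys if include_references else m.sample_keys
    data = m.values[keys].dropna(axis=0)
    if k > min(data.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(data.shape)}")
    X = data.to_numpy()
    X = X - X.mean(axis=1, keepdims=True)  # row (protein) mean across samples
    total_var = float(np.sum(X * X))
    if total_var == 0:
        raise ValueError("degenerate input: zero variance after row centering")
    # channels are the observations; project each channel on the left factors
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = Vt[:k].T * s[:k]
    var_frac = (s**2 / np.sum(s**2))[:k]
    frame = pd.DataFrame(scores, index=keys, columns=[f"PC{i+1}" for i in range(k)])
    return PcaResult(scores=frame, variance_fraction=var_frac)


def correlation_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of the given column profiles.

    Constant columns yield NA rows/columns with a warning.
    """
    stds = columns.std(axis=0, skipna=True)
    constant = stds.index[stds == 0].tolist()
    if constant:
        warnings.warn(f"constant columns yield NA correlations: {constant[:5]}")
    corr = columns.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def sample_correlation(m: LogMatrix, include_references: bool = False) -> pd.DataFrame:
    keys = m.channel_keys if include_references else m.sample_keys
    return correlation_matrix(m.values[keys])


def ratio_correlation(lfc_table: pd.DataFrame) -> pd.DataFrame:
    """Correlation of per-cell-line 3D-vs-2D log2-ratio vectors."""
    return correlation_matrix(lfc_table)
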