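"""Preprocessing: detection-call filtering, probe-to-gene
summarization, row z-scoring, and log2 fold changes.

All standard deviations use the sample (n-1) denominator.  Z-scored
matrices feed the state-scoring and network diagnostics downstream;
their correlations are insensitive to the denominator convention but
the z values themselves are not, so the convention is fixed here.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, FoldChangeTable, ProbeAnnotation, ValidationError

logger = logging.getLogger("txstate")


def present_filter(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    min_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Retain probes detected ("present") in strictly more than
    ``min_fraction`` of samples.

    The default reproduces the usual microarray background filter:
    probes called present in greater than 50% of samples.  The
    inequality is strict, so composing two filters equals filtering
    once at the larger threshold.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    missing = [p for p in matrix.probe_ids if p not in annotation.present.index]
    if missing:
        raise ValidationError(f"probes without annotation: {missing[:10]}")
    fractions = annotation.present_fraction.reindex(matrix.data.index)
    keep = fractions > min_fraction
    kept = matrix.data.loc[keep.to_numpy()]
    logger.info(
        "present filter (> %.0f%%): kept %d of %d probes",
        100 * min_fraction,
        kept.shape[0],
        matrix.n_probes,
    )
    return ExpressionMatrix(kept, scale_note=matrix.scale_note)


def summarize_probes_to_genes(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    mode: str = "weighted_present",
) -> ExpressionMatrix:
    """Collapse multiple probe sets per gene to a single expression row.

    ``weighted_present``
        Weighted average of probe values with weights equal to each
        probe's present-call fraction — genes with several probe sets
        contribute one value, weighted toward reliably detected probes.
    ``simple_mean``
        Unweighted mean of per-probe mean-centered log2 rows (the
        convention used for averaging the two BDNF probe sets).

    Probes without a gene symbol are dropped (count logged).
    """
    if mode not in ("weighted_present", "simple_mean"):
        raise ValueError(f"unknown summarization mode {mode!r}")
    symbols = annotation.gene_symbol.reindex(matrix.data.index)
    has_gene = symbols.notna() & (symbols.astype(str).str.strip() != "")
    n_dropped = int((~has_gene).sum())
    if n_dropped:
        logger.info("probe->gene summarization: dropped %d probes without gene symbol", n_dropped)
    data = matrix.data.loc[has_gene.to_numpy()]
    symbols = symbols[has_gene].astype(str)

    if mode == "weighted_present":
        weights = annotation.present_fraction.reindex(data.index).to_numpy()
        weight_sums = pd.Series(weights, index=data.index).groupby(symbols).sum()
        zero_genes = weight_sums.index[weight_sums == 0].tolist()
        if zero_genes:
            raise ValidationError(
                "genes whose probes all have zero present fraction: "
                f"{zero_genes[:10]}"
            )
        weighted = data.mul(weights, axis=0)
        summarized = weighted.groupby(symbols).sum().div(weight_sums, axis=0)
    else:
        centered = data.sub(data.mean(axis=1), axis=0)
        summarized = centered.groupby(symbols).mean()

    summarized = summarized.sort_index()
    return ExpressionMatrix(summarized, scale_note=f"{matrix.scale_note}; gene-level ({mode})")


#: Rows whose sample SD falls below this fraction of their magnitude
#: are treated as flat: identical values can acquire an SD of order
#: machine epsilon times their mean through summation rounding.
FLAT_ROW_RTOL = 1e-10


def _flat_rows(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1, ddof=1)
    scale = np.maximum(np.abs(values).max(axis=1), 1.0)
    return sd <= FLAT_ROW_RTOL * scale


def constant_row_mask(matrix: ExpressionMatrix) -> pd.Series:
    """Boolean mask of rows with (numerically) zero sample variance."""
    return pd.Series(_flat_rows(matrix.values), index=matrix.data.index)


def drop_constant_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop flat probes (zero sample variance), logging how many.

    Flat probes carry no covariance information and make z-scoring
    undefined; synthetic and heavily filtered data can contain them.
    """
    mask = constant_row_mask(matrix)
    n_const = int(mask.sum())
    if n_const:
        logger.warning("dropping %d constant probe row(s) before z-scoring", n_const)
    return ExpressionMatrix(matrix.data.loc[~mask.to_numpy()], scale_note=matrix.scale_note)


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each probe row to mean 0, sample SD 1.

    Raises on constant rows, listing the probe IDs; callers that expect
    flat probes should :func:`drop_constant_rows` first.
    """
    values = matrix.values
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(_flat_rows(values))
    if flat.size:
        ids = [matrix.probe_ids[i] for i in flat[:10]]
        raise ValidationError(f"constant probe row(s), z-score undefined: {ids}")
    z = (values - means) / sds
    frame = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, scale_note=f"{matrix.scale_note}; z-scored")


def log_fold_change(
    matrix: ExpressionMatrix,
    samples_treated: Sequence[str],
    samples_control: Sequence[str],
) -> FoldChangeTable:
    """Per-probe log2 fold change (treated mean - control mean) with a
    two-sided Welch t-test p-value.

    The matrix is assumed to already be on the log2 scale, so the group
    mean difference *is* the log2 fold change.  With a singleton group
    the fold change is still returned but p-values are NaN (flagged
    unavailable).  Probes with identical values in both groups get
    p = 1 (no evidence of change).
    """
    treated = list(samples_treated)
    control = list(samples_control)
    overlap = sorted(set(treated) & set(control))
    if overlap:
        raise ValidationError(f"treated and control groups overlap: {overlap}")
    if not treated or not control:
        raise ValidationError("treated and control groups must be non-empty")

    x = matrix.subset_samples(treated).values
    y = matrix.subset_samples(control).values
    fc = x.mean(axis=1) - y.mean(axis=1)

    if len(treated) < 2 or len(control) < 2:
        logger.warning("group of size 1: fold changes returned, p-values unavailable")
        p = np.full(matrix.n_probes, np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
        # Zero-variance probes with equal means carry no evidence.
        p = np.where(np.isnan(p) & (fc == 0), 1.0, p)

    table = pd.DataFrame(
        {"log2_fc": fc, "p_value": p, "direction": np.sign(fc)},
        index=matrix.data.index,
    )
    return FoldChangeTable(table=table, treated_ids=treated, control_ids=control)
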