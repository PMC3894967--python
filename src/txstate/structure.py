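"""System-level diagnostics around the state score.

Three views of the same claim — that PCA1 tracks a single dominant,
hierarchically organized expression program:

* **Connectivity**: a gene is "connected" to another when their
  expression profiles cross-correlate significantly (p < 0.001);
  connectivity is the number of connections divided by the total
  number of genes analyzed.  In a hierarchical system, highly
  connected genes sit near the top and follow the global state most
  closely.
* **Euclidean distance**: distance of each transcriptome from the one
  with the lowest PCA1.  If PCA1 measures position along a single
  program, this global dissimilarity is a linear function of PCA1.
* **Cross-region concordance**: log2 fold changes and PCA1-correlated
  gene sets computed independently in dorsal and ventral dentate
  should agree in magnitude and direction.

Correlation p-values use the exact t transform
``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom,
two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, FoldChangeTable, ValidationError
from .state import StateScores

logger = logging.getLogger("txstate")


@dataclass
class ConnectivityTable:
    """Per-gene connection counts and agreement with PCA1.

    ``table`` has columns ``n_connections``, ``connectivity``
    (= n_connections / G for G genes analyzed), ``r_with_pca1`` and
    ``p_with_pca1``, indexed by gene/probe ID.
    """

    table: pd.DataFrame
    alpha: float
    n_genes: int
    seed: int | None = None

    def __post_init__(self) -> None:
        g = self.n_genes
        counts = self.table["n_connections"].to_numpy()
        if counts.max(initial=0) > g - 1:
            raise ValidationError("a gene cannot connect to more than G-1 others")
        expected = counts / g
        if not np.allclose(self.table["connectivity"].to_numpy(), expected):
            raise ValidationError("connectivity must equal n_connections / n_genes")


@dataclass
class ConcordanceReport:
    """Cross-region agreement of per-probe fold changes.

    Percentages are on the 0-100 scale.  ``pct_same_dir_any`` is
    computed over probes significant in at least one region (after
    excluding zero fold changes, which carry no direction);
    ``pct_same_dir_both`` over probes significant in both.
    """

    pearson_r_fc: float
    pct_sig_any: float
    pct_sig_both: float
    pct_same_dir_any: float
    pct_same_dir_both: float
    alpha: float
    n_probes: int

    def __post_init__(self) -> None:
        for name in ("pct_sig_any", "pct_sig_both", "pct_same_dir_any", "pct_same_dir_both"):
            value = getattr(self, name)
            if not (np.isnan(value) or 0 <= value <= 100):
                raise ValidationError(f"{name} must lie in [0, 100], got {value}")
        if self.pct_sig_both > self.pct_sig_any + 1e-9:
            raise ValidationError("pct_sig_both cannot exceed pct_sig_any")

    def to_dict(self) -> dict:
        return {
            "pearson_r_fc": self.pearson_r_fc,
            "pct_sig_any": self.pct_sig_any,
            "pct_sig_both": self.pct_sig_both,
            "pct_same_dir_any": self.pct_same_dir_any,
            "pct_same_dir_both": self.pct_same_dir_both,
            "alpha": self.alpha,
            "n_probes": self.n_probes,
        }


@dataclass
class DistanceProfile:
    """Euclidean distance of each transcriptome from the lowest-state
    one, and its linearity with PCA1."""

    sample_ids: list[str]
    distance: np.ndarray
    reference_sample: str
    linearity_r: float

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        if (self.distance < 0).any():
            raise ValidationError("distances must be non-negative")
        ref_idx = self.sample_ids.index(self.reference_sample)
        if self.distance[ref_idx] != 0:
            raise ValidationError("reference sample must have distance 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.distance, index=self.sample_ids, name="distance")


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations via the t transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _align_scores(z: ExpressionMatrix, scores: StateScores) -> np.ndarray:
    if list(scores.sample_ids) != z.sample_ids:
        raise ValidationError("scores and matrix index different samples")
    return scores.pca1


def gene_connectivity(
    z: ExpressionMatrix,
    scores: StateScores,
    alpha: float = 0.001,
    max_genes: int | None = 5000,
    seed: int | None = 0,
    method: str = "pearson",
) -> ConnectivityTable:
    """Connection counts from the thresholded cross-correlation
    adjacency matrix, plus each gene's correlation with PCA1.

    Two genes are connected when the two-sided p-value of their
    cross-correlation is below ``alpha`` (default 0.001).  At full
    transcriptome scale the pairwise matrix is quadratic in the number
    of genes, so by default a seeded uniform subsample of ``max_genes``
    genes is analyzed; pass ``max_genes=None`` for the full matrix.
    ``method`` selects Pearson (default) or Spearman cross-correlations.
    """
    n = z.n_samples
    if n < 4:
        raise ValidationError("connectivity needs at least 4 samples (df >= 2)")
    if max_genes is not None and max_genes < 2:
        raise ValueError("max_genes must be at least 2")
    pca1 = _align_scores(z, scores)

    data = z.data
    if max_genes is not None and z.n_probes > max_genes:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(z.n_probes, size=max_genes, replace=False))
        data = data.iloc[idx]
        logger.info("connectivity: subsampled %d of %d genes (seed=%s)", max_genes, z.n_probes, seed)

    values = data.to_numpy()
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    p = correlation_pvalues(corr, n)
    np.fill_diagonal(p, 1.0)  # self-correlation is not a connection
    connected = p < alpha
    counts = connected.sum(axis=1)
    g = values.shape[0]

    centered = values - values.mean(axis=1, keepdims=True)
    pc = pca1 - pca1.mean()
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((pc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r_pca1 = centered @ pc / denom
    r_pca1 = np.nan_to_num(r_pca1, nan=0.0)
    p_pca1 = correlation_pvalues(r_pca1, n)

    table = pd.DataFrame(
        {
            "n_connections": counts,
            "connectivity": counts / g,
            "r_with_pca1": r_pca1,
            "p_with_pca1": p_pca1,
        },
        index=data.index,
    )
    return ConnectivityTable(table=table, alpha=alpha, n_genes=g, seed=seed)


def connectivity_state_curve(
    table: ConnectivityTable, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Binned connectivity vs |r with PCA1| curve plus its Spearman r.

    Genes are split into equal-count quantile bins of connectivity
    (connectivity is heavy-tailed, so equal-width bins would leave most
    bins empty); per-bin means of connectivity and |r with PCA1| are
    returned together with the gene-level Spearman correlation between
    the two.  A positive correlation is the signature of a hierarchy:
    highly connected genes track the global state most closely.
    """
    if table.table.empty:
        raise ValidationError("connectivity table is empty")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    frame = table.table
    conn = frame["connectivity"]
    abs_r = frame["r_with_pca1"].abs()

    if conn.nunique() == 1:
        logger.warning("all connectivities identical; returning a single bin")
        binned = pd.DataFrame(
            {"mean_connectivity": [conn.mean()], "mean_abs_r_with_pca1": [abs_r.mean()],
             "n_genes": [len(conn)]},
            index=pd.Index([0], name="bin"),
        )
        return binned, float("nan")

    ranks = conn.rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, conn.nunique()), labels=False)
    binned = pd.DataFrame(
        {
            "mean_connectivity": conn.groupby(bins).mean(),
            "mean_abs_r_with_pca1": abs_r.groupby(bins).mean(),
            "n_genes": conn.groupby(bins).size(),
        }
    )
    binned.index.name = "bin"
    rho = stats.spearmanr(conn, abs_r).statistic
    return binned, float(rho)


def euclidean_profile(z: ExpressionMatrix, scores: StateScores) -> DistanceProfile:
    """Distance of every transcriptome from the lowest-PCA1 one.

    The reference is the sample with minimum PCA1 (ties broken by
    lexicographically smallest sample ID, logged); distances are
    Euclidean over all probes of the standardized matrix, and
    ``linearity_r`` is the Pearson correlation between distance and
    PCA1 across samples.
    """
    pca1 = _align_scores(z, scores)
    min_val = pca1.min()
    tied = [sid for sid, v in zip(z.sample_ids, pca1) if v == min_val]
    if len(tied) > 1:
        logger.warning("tie for minimum PCA1 among %s; using %s", tied, min(tied))
    reference = min(tied)
    ref_idx = z.sample_ids.index(reference)

    diffs = z.values - z.values[:, [ref_idx]]
    distance = np.sqrt((diffs**2).sum(axis=0))
    linearity_r = float(np.corrcoef(distance, pca1)[0, 1])
    return DistanceProfile(
        sample_ids=z.sample_ids,
        distance=distance,
        reference_sample=reference,
        linearity_r=linearity_r,
    )


def pca1_gene_correlations(
    z: ExpressionMatrix, scores: StateScores, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlation of every probe's profile with PCA1.

    Returns a frame with columns ``r``, ``p``, ``significant`` (at
    ``alpha``, uncorrected per-probe testing) and ``direction``
    (sign of r), indexed by probe ID.
    """
    n = z.n_samples
    if n < 4:
        raise ValidationError("needs at least 4 samples")
    pca1 = _align_scores(z, scores)

    values = z.values
    centered = values - values.mean(axis=1, keepdims=True)
    pc = pca1 - pca1.mean()
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((pc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = centered @ pc / denom
    r = np.nan_to_num(r, nan=0.0)
    p = correlation_pvalues(r, n)
    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "significant": p < alpha,
            "direction": np.sign(r),
        },
        index=z.data.index,
    )


def regional_concordance(
    fc_dorsal: FoldChangeTable,
    fc_ventral: FoldChangeTable,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Agreement of fold-change responses between the two regions.

    Computes the cross-region Pearson r of per-probe log2 fold changes
    and four percentages: probes significant (p < ``alpha``) in at
    least one region, in both regions, and — among those — the share
    changing in the same direction in the other region.  Probes with a
    fold change of exactly 0 in either region are excluded from the
    direction percentages (a zero change has no direction; count
    logged).
    """
    d = fc_dorsal.table
    v = fc_ventral.table
    if set(d.index) != set(v.index):
        diff = sorted(set(d.index) ^ set(v.index))
        raise ValidationError(f"fold-change tables cover different probes: {diff[:10]}")
    v = v.reindex(d.index)

    n_probes = len(d)
    r_fc = float(np.corrcoef(d["log2_fc"], v["log2_fc"])[0, 1])

    sig_d = (d["p_value"] < alpha).to_numpy()
    sig_v = (v["p_value"] < alpha).to_numpy()
    sig_any = sig_d | sig_v
    sig_both = sig_d & sig_v
    pct_sig_any = 100.0 * sig_any.mean()
    pct_sig_both = 100.0 * sig_both.mean()

    directed = (d["log2_fc"].to_numpy() != 0) & (v["log2_fc"].to_numpy() != 0)
    n_undirected = int((~directed & sig_any).sum())
    if n_undirected:
        logger.info(
            "direction concordance: excluded %d significant probe(s) with zero fold change",
            n_undirected,
        )
    same_dir = np.sign(d["log2_fc"].to_numpy()) == np.sign(v["log2_fc"].to_numpy())

    any_mask = sig_any & directed
    both_mask = sig_both & directed
    pct_same_any = 100.0 * same_dir[any_mask].mean() if any_mask.any() else float("nan")
    pct_same_both = 100.0 * same_dir[both_mask].mean() if both_mask.any() else float("nan")

    return ConcordanceReport(
        pearson_r_fc=r_fc,
        pct_sig_any=pct_sig_any,
        pct_sig_both=pct_sig_both,
        pct_same_dir_any=float(pct_same_any),
        pct_same_dir_both=float(pct_same_both),
        alpha=alpha,
        n_probes=n_probes,
    )
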