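"""Global expression system-state scoring.

The state of a transcriptome is summarized by the first principal
component score (PCA1) of the z-scored probes x samples matrix, with
samples as observations and probes as variables — one score per array.
PCA1 behaves as an eigengene for the dominant covarying program: in the
study design this package targets it captures roughly a fifth of total
expression variance, and scores computed from small independent probe
subsets agree nearly perfectly, which is the robustness property the
subsampling protocol here quantifies.

Sign conventions: a principal component's sign is mathematically
arbitrary, so every score vector carries an explicit orientation
record.  The default rule orients the all-probe reference so that
treated samples score higher than controls (when treatment labels
exist), and aligns every probe-subset score to that reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError
from .preprocess import drop_constant_rows, zscore_rows

logger = logging.getLogger("txstate")

ROW_MEAN_TOL = 1e-6


@dataclass
class StateScores:
    """Per-sample PCA1 scores with variance-explained shares.

    ``pca1`` is normalized to unit sample standard deviation (scores
    are only ever used in correlations, which are scale-invariant; a
    fixed scale makes scores comparable across probe subsets).
    ``variance_explained`` holds the fractional shares of components
    1..k.  ``orientation`` records the sign rule applied and the sign
    it produced.  ``loadings`` optionally carries the first component's
    probe loadings (used by the largest-loading sign rule).
    """

    sample_ids: list[str]
    pca1: np.ndarray
    variance_explained: np.ndarray
    orientation: dict = field(default_factory=dict)
    loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pca1 = np.asarray(self.pca1, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if self.pca1.shape != (len(self.sample_ids),):
            raise ValidationError("pca1 length must match sample_ids")
        ve = self.variance_explained
        if ve.size and (ve.min() < -1e-12 or ve.max() > 1 + 1e-12):
            raise ValidationError("variance_explained entries must lie in [0, 1]")
        if ve.size and np.any(np.diff(ve) > 1e-12):
            raise ValidationError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValidationError("variance_explained must sum to at most 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.pca1, index=self.sample_ids, name="pca1")

    def flipped(self, reason: str) -> "StateScores":
        orientation = dict(self.orientation)
        orientation.update(rule=reason, sign=-orientation.get("sign", 1))
        return StateScores(
            sample_ids=list(self.sample_ids),
            pca1=-self.pca1,
            variance_explained=self.variance_explained.copy(),
            orientation=orientation,
            loadings=None if self.loadings is None else -self.loadings,
        )


@dataclass
class ProbePartition:
    """Disjoint equal-size probe groups for subsampling analyses."""

    groups: list[list[str]]
    mode: str
    group_size: int
    seed: int | None = None

    def __post_init__(self) -> None:
        flat = list(itertools.chain.from_iterable(self.groups))
        if len(flat) != len(set(flat)):
            raise ValidationError("partition groups are not disjoint")
        for i, group in enumerate(self.groups):
            if len(group) != self.group_size:
                raise ValidationError(
                    f"group {i} has {len(group)} probes, expected {self.group_size}"
                )

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class SubsampleReport:
    """Concordance of PCA1 across independent probe groups.

    ``pairwise_r`` is the symmetric Pearson correlation matrix of the
    sign-aligned per-group score vectors.  Alignment guarantees each
    group correlates non-negatively with the *reference*; off-diagonal
    entries between two groups are not themselves guaranteed
    non-negative.
    """

    group_scores: list[StateScores]
    pairwise_r: np.ndarray
    min_r: float
    median_r: float

    def __post_init__(self) -> None:
        r = np.asarray(self.pairwise_r, dtype=float)
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValidationError("pairwise_r must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-9):
            raise ValidationError("pairwise_r diagonal must be 1")
        if r.min() < -1 - 1e-12 or r.max() > 1 + 1e-12:
            raise ValidationError("pairwise_r entries must lie in [-1, 1]")
        self.pairwise_r = r

    def to_dict(self) -> dict:
        return {
            "n_groups": len(self.group_scores),
            "min_r": self.min_r,
            "median_r": self.median_r,
            "pairwise_r": self.pairwise_r.tolist(),
        }


def _check_standardized(z: ExpressionMatrix) -> None:
    means = z.values.mean(axis=1)
    if np.abs(means).max() > ROW_MEAN_TOL:
        raise ValidationError(
            "matrix rows are not standardized (row mean beyond "
            f"{ROW_MEAN_TOL:g}); z-score first"
        )


def compute_pca1(z: ExpressionMatrix, n_components: int = 4) -> StateScores:
    """First principal component score per sample of a z-scored matrix.

    Samples are observations and probes variables, so the score vector
    has one entry per array.  Computed by singular value decomposition
    of the standardized matrix; the variance-explained share of
    component i is lambda_i / sum(lambda).  The returned score has unit
    sample standard deviation, and the sign is fixed so the loading
    with largest absolute value is positive (recorded in
    ``orientation``; see :func:`orient_scores` for anchor-based rules).
    """
    if z.n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if z.n_probes < 2:
        raise ValidationError("PCA requires at least 2 probes")
    _check_standardized(z)

    # X: samples x probes, columns centered (rows of z are z-scored).
    x = z.values.T
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    lam = s**2
    total = lam.sum()
    if total == 0:
        raise ValidationError("matrix has no variance")
    k = min(n_components, lam.size)
    variance_explained = lam[:k] / total

    scores = u[:, 0] * s[0]
    loadings = vt[0]
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate first component (zero score variance)")
    scores = scores / sd

    # Deterministic default sign: largest-|loading| probe loads positively.
    anchor_idx = int(np.argmax(np.abs(loadings)))
    sign = 1
    if loadings[anchor_idx] < 0:
        sign = -1
        scores = -scores
        loadings = -loadings
    orientation = {
        "rule": "largest_loading",
        "anchor_probe": z.probe_ids[anchor_idx],
        "sign": sign,
    }
    return StateScores(
        sample_ids=z.sample_ids,
        pca1=scores,
        variance_explained=variance_explained,
        orientation=orientation,
        loadings=loadings,
    )


def score_matrix(matrix: ExpressionMatrix, n_components: int = 4) -> StateScores:
    """Convenience: drop flat probes, z-score, and compute PCA1."""
    return compute_pca1(zscore_rows(drop_constant_rows(matrix)), n_components=n_components)


def orient_scores(
    scores: StateScores,
    anchor: Sequence[float] | str = "largest_loading",
) -> StateScores:
    """Fix the sign of a score vector against an anchor.

    With an anchor vector (one value per sample), the score is flipped
    so its Pearson correlation with the anchor is non-negative; an
    exactly-zero correlation leaves the sign unchanged with a warning.
    With the token ``"largest_loading"`` the default loading-based rule
    is (re)applied.
    """
    if isinstance(anchor, str):
        if anchor != "largest_loading":
            raise ValueError(f"unknown orientation rule {anchor!r}")
        if scores.loadings is None:
            raise ValidationError("scores carry no loadings; cannot apply loading rule")
        idx = int(np.argmax(np.abs(scores.loadings)))
        if scores.loadings[idx] < 0:
            return scores.flipped("largest_loading")
        return scores

    anchor = np.asarray(anchor, dtype=float)
    if anchor.shape != scores.pca1.shape:
        raise ValidationError("anchor length must match number of samples")
    if anchor.std() == 0:
        raise ValidationError("anchor vector is constant; orientation undefined")
    r = float(np.corrcoef(scores.pca1, anchor)[0, 1])
    if r < 0:
        return scores.flipped("anchor_alignment")
    if r == 0:
        logger.warning("anchor exactly orthogonal to scores; sign left unchanged")
    return scores


def orient_to_treatment(
    scores: StateScores, treated_ids: Sequence[str], control_ids: Sequence[str]
) -> StateScores:
    """Orient so the mean score of treated samples exceeds controls.

    This is the reference convention: the treatment arm (chronic
    fluoxetine on top of corticosterone) shifts the state upward, and
    behavioral readouts then correlate negatively with state.
    """
    series = scores.as_series()
    diff = series.loc[list(treated_ids)].mean() - series.loc[list(control_ids)].mean()
    if diff < 0:
        flipped = scores.flipped("treatment_means")
        flipped.orientation["detail"] = "flipped so treated mean > control mean"
        return flipped
    return scores


def partition_probes(
    probe_ids: Sequence[str],
    group_size: int,
    n_groups: int | str = "max",
    mode: str = "ordered",
    seed: int | None = None,
) -> ProbePartition:
    """Split probes into disjoint equal-size groups.

    ``ordered`` takes consecutive blocks in the given probe order
    (mirroring grouping by probe-set ID number: group 1 is probes
    1..group_size, group 2 the next block, and so on); ``shuffled``
    permutes with ``seed`` first.  Leftover probes that cannot fill a
    complete group are discarded.
    """
    probe_ids = list(probe_ids)
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    max_groups = len(probe_ids) // group_size
    if n_groups == "max":
        n_groups = max_groups
    if not isinstance(n_groups, int) or n_groups < 1:
        raise ValueError(f"n_groups must be a positive integer or 'max', got {n_groups!r}")
    if n_groups > max_groups:
        raise ValidationError(
            f"cannot form {n_groups} groups of {group_size} from {len(probe_ids)} "
            f"probes (max feasible: {max_groups})"
        )
    if mode == "shuffled":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(probe_ids))
        probe_ids = [probe_ids[i] for i in order]
    elif mode != "ordered":
        raise ValueError(f"unknown partition mode {mode!r}")
    groups = [
        probe_ids[i * group_size : (i + 1) * group_size] for i in range(n_groups)
    ]
    n_discarded = len(probe_ids) - n_groups * group_size
    if n_discarded:
        logger.info("partition: %d leftover probes discarded", n_discarded)
    return ProbePartition(groups=groups, mode=mode, group_size=group_size, seed=seed)


def subsample_state_concordance(
    z: ExpressionMatrix,
    partition: ProbePartition,
    reference: StateScores | None = None,
    zscore_within_group: bool = True,
) -> SubsampleReport:
    """PCA1 concordance across independent probe groups.

    Computes PCA1 separately within each partition group, aligns every
    group's sign to the reference score (default: PCA1 on all probes),
    and reports the full pairwise Pearson correlation matrix of the
    group score vectors with its minimum and median off-diagonal
    entries.

    ``zscore_within_group`` re-standardizes each group's rows before
    its PCA (the default, matching per-group analysis of z-scored
    data); on an already z-scored input this is a numerical no-op but
    matters when callers pass raw matrices.
    """
    all_probes = set(z.probe_ids)
    for i, group in enumerate(partition.groups):
        if not set(group) <= all_probes:
            raise ValidationError(f"partition group {i} contains probes absent from matrix")

    if reference is None:
        reference = compute_pca1(z)
    anchor = reference.pca1

    group_scores: list[StateScores] = []
    for i, group in enumerate(partition.groups):
        sub = z.subset_probes(group)
        sub = drop_constant_rows(sub)
        if sub.n_probes < 2:
            raise ValidationError(f"group {i} has fewer than 2 usable probes")
        if zscore_within_group:
            sub = zscore_rows(sub)
        scores = compute_pca1(sub)
        group_scores.append(orient_scores(scores, anchor))

    stacked = np.vstack([s.pca1 for s in group_scores])
    pairwise = np.corrcoef(stacked)
    pairwise = np.atleast_2d(pairwise)
    off_diag = pairwise[~np.eye(pairwise.shape[0], dtype=bool)]
    return SubsampleReport(
        group_scores=group_scores,
        pairwise_r=pairwise,
        min_r=float(off_diag.min()) if off_diag.size else 1.0,
        median_r=float(np.median(off_diag)) if off_diag.size else 1.0,
    )
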