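"""State-behavior association with a normality-gated correlation rule.

Behavioral readouts — immobility in the forced swim test (FST) and
latency to eat in the novelty suppressed feeding test (NSF, censored at
the 8-minute ceiling) — are related to per-sample state scores.  Each
correlation is Pearson when both variables pass a Shapiro-Wilk
normality check and Spearman otherwise, so heavy-tailed or censored
behavior values fall back to ranks automatically.

Animals that respond to the antidepressant in exactly one of the two
tests ("ambiguous responders") can be flagged and excluded before the
association, mirroring a design in which clearly responding or
non-responding animals carry the state-behavior signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import SampleInfo, ValidationError
from .state import StateScores

logger = logging.getLogger("txstate")


@dataclass
class AssociationResult:
    """One correlation between two variables, with the method chosen by
    the normality gate recorded."""

    x_name: str
    y_name: str
    method: str
    r: float
    p_value: float
    n: int
    normality_p: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "x": self.x_name,
            "y": self.y_name,
            "method": self.method,
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
            "normality_p_x": self.normality_p[0],
            "normality_p_y": self.normality_p[1],
        }


@dataclass
class ResponderFlags:
    """Per-animal response flags under a threshold rule.

    ``ambiguous`` is true when the animal responds on exactly one of
    the two tests.
    """

    animal_id: str
    fst_responder: bool
    nsf_responder: bool
    ambiguous: bool
    thresholds: dict

    def __post_init__(self) -> None:
        if self.ambiguous != (self.fst_responder ^ self.nsf_responder):
            raise ValidationError("ambiguous must equal fst_responder XOR nsf_responder")


def auto_correlate(
    x: Sequence[float],
    y: Sequence[float],
    normality_alpha: float = 0.05,
    x_name: str = "x",
    y_name: str = "y",
) -> AssociationResult:
    """Correlate two vectors, choosing Pearson or Spearman by normality.

    Shapiro-Wilk is run on each vector; Pearson is used only when both
    p-values exceed ``normality_alpha``, otherwise Spearman (with
    average ranks for ties).  Two-sided p-value for the chosen
    statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if x.size < 4:
        raise ValidationError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")

    sw_x = float(stats.shapiro(x).pvalue)
    sw_y = float(stats.shapiro(y).pvalue)
    if sw_x > normality_alpha and sw_y > normality_alpha:
        method = "pearson"
        result = stats.pearsonr(x, y)
    else:
        method = "spearman"
        result = stats.spearmanr(x, y)
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        method=method,
        r=float(result.statistic),
        p_value=float(result.pvalue),
        n=int(x.size),
        normality_p=(sw_x, sw_y),
    )


def group_compare(
    values_treated: Sequence[float],
    values_control: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided two-sample t-test on a behavioral measure.

    Welch (unequal variances) by default; pass ``equal_var=True`` for
    the pooled-variance Student test.  Returns (t, p, (mean_treated,
    mean_control)).
    """
    a = np.asarray(values_treated, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t) and np.isclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0  # zero-variance groups with equal means
    return float(t), float(p), (float(a.mean()), float(b.mean()))


def flag_ambiguous_responders(
    info: Sequence[SampleInfo],
    controls: Sequence[SampleInfo],
    rule: Mapping[str, float] | None = None,
) -> list[ResponderFlags]:
    """Flag treated animals that respond on exactly one behavioral test.

    Response means a *lower* value than threshold on that test (lower
    immobility / shorter latency = antidepressant-like response).  The
    default rule thresholds each test at the control-arm median; pass
    ``rule={"fst": ..., "nsf": ...}`` to override.  Per-animal behavior
    is taken from the first sample seen for the animal (both regional
    samples of an animal share its behavior scores).
    """
    if not controls:
        raise ValidationError("control arm is empty; thresholds undefined")
    if not info:
        raise ValidationError("treated arm is empty")

    if rule is None:
        ctrl_animals: dict[str, SampleInfo] = {}
        for s in controls:
            ctrl_animals.setdefault(s.animal_id, s)
        fst_cut = float(np.median([s.fst_immobility for s in ctrl_animals.values()]))
        nsf_cut = float(np.median([s.nsf_latency for s in ctrl_animals.values()]))
        rule_used = {"fst": fst_cut, "nsf": nsf_cut, "source": "control_median"}
    else:
        rule_used = {"fst": float(rule["fst"]), "nsf": float(rule["nsf"]), "source": "explicit"}

    flags: list[ResponderFlags] = []
    seen: set[str] = set()
    for s in info:
        if s.animal_id in seen:
            continue
        seen.add(s.animal_id)
        fst_resp = s.fst_immobility < rule_used["fst"]
        nsf_resp = s.nsf_latency < rule_used["nsf"]
        flags.append(
            ResponderFlags(
                animal_id=s.animal_id,
                fst_responder=fst_resp,
                nsf_responder=nsf_resp,
                ambiguous=fst_resp ^ nsf_resp,
                thresholds=dict(rule_used),
            )
        )
    n_amb = sum(f.ambiguous for f in flags)
    logger.info("responder flags: %d of %d treated animals ambiguous", n_amb, len(flags))
    return flags


def behavior_state_report(
    scores_by_region: Mapping[str, StateScores],
    info: Sequence[SampleInfo],
    exclude_ambiguous: bool = False,
    normality_alpha: float = 0.05,
) -> list[AssociationResult]:
    """State-behavior correlations for each region x behavior pair.

    For each region's score vector, correlates PCA1 with FST immobility
    and NSF latency across that region's samples via
    :func:`auto_correlate`.  With ``exclude_ambiguous`` the
    control-median responder rule is applied to the treated arm and
    ambiguous animals are dropped before correlating.  NSF values at
    the 480 s ceiling are kept as-is (average ranks handle the ties);
    their count is logged.
    """
    by_id = {s.sample_id: s for s in info}
    excluded: set[str] = set()
    if exclude_ambiguous:
        treated = [s for s in info if s.treatment == "CORT_FLX"]
        controls = [s for s in info if s.treatment == "CORT"]
        flags = flag_ambiguous_responders(treated, controls)
        excluded = {f.animal_id for f in flags if f.ambiguous}
        if excluded:
            logger.info("excluding ambiguous animals: %s", sorted(excluded))

    results: list[AssociationResult] = []
    for region, scores in scores_by_region.items():
        rows = []
        for sid, value in zip(scores.sample_ids, scores.pca1):
            sample = by_id.get(sid)
            if sample is None:
                raise ValidationError(f"scored sample {sid!r} has no metadata")
            if sample.animal_id in excluded:
                continue
            rows.append((value, sample.fst_immobility, sample.nsf_latency))
        if len(rows) < 4:
            raise ValidationError(
                f"region {region!r}: fewer than 4 usable animals after exclusion"
            )
        pca1, fst, nsf = (np.array(col) for col in zip(*rows))
        n_ceiling = int((nsf >= 480).sum())
        if n_ceiling:
            logger.info("region %s: %d NSF value(s) at the 480 s ceiling", region, n_ceiling)
        results.append(
            auto_correlate(pca1, fst, normality_alpha, x_name=f"pca1_{region}", y_name="fst_immobility")
        )
        results.append(
            auto_correlate(pca1, nsf, normality_alpha, x_name=f"pca1_{region}", y_name="nsf_latency")
        )
    return results
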