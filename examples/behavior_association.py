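"""Relating system state to antidepressant-sensitive behaviors.

Scores both regions of a default study, orients the scores so that
treated animals score higher, and correlates PCA1 with forced-swim
immobility and novelty-suppressed-feeding latency.  The correlation
method is chosen per pair by a Shapiro-Wilk normality gate (Pearson if
both variables look normal, Spearman otherwise).  Negative
correlations mean higher state goes with more antidepressant-like
behavior.  Ambiguous responders (animals responding on exactly one
test) can be excluded first.
"""

from txstate import (
    GeneratorParams,
    behavior_state_report,
    flag_ambiguous_responders,
    generate_study,
    score_matrix,
)
from txstate.state import orient_to_treatment

study = generate_study(GeneratorParams(seed=1))
scores = {}
for region in ("dorsal", "ventral"):
    samples = study.samples_for_region(region)
    treated = [s.sample_id for s in samples if s.treatment == "CORT_FLX"]
    control = [s.sample_id for s in samples if s.treatment == "CORT"]
    scores[region] = orient_to_treatment(
        score_matrix(study.expression[region]), treated, control
    )

treated_info = [s for s in study.info if s.treatment == "CORT_FLX"]
control_info = [s for s in study.info if s.treatment == "CORT"]
flags = flag_ambiguous_responders(treated_info, control_info)
print(f"ambiguous responders: {sum(f.ambiguous for f in flags)} "
      f"of {len(flags)} treated animals")

for result in behavior_state_report(scores, study.info, exclude_ambiguous=True):
    print(
        f"{result.x_name} vs {result.y_name}: {result.method} "
        f"r = {result.r:+.2f} (p = {result.p_value:.2g}, n = {result.n})"
    )
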