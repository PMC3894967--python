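"""Cross-region concordance of treatment fold changes.

Computes per-probe log2 fold changes (treated minus control) in dorsal
and ventral dentate separately and quantifies how well the two regions
agree: the correlation of fold changes, the share of probes reaching
significance in one or both regions, and the share changing in the
same direction.  High direction agreement with moderate per-probe
significance is what a single shared system-state response looks like
through noisy individual measurements.
"""

from txstate import GeneratorParams, generate_study, log_fold_change, regional_concordance

study = generate_study(GeneratorParams(seed=1))
tables = {}
for region in ("dorsal", "ventral"):
    samples = study.samples_for_region(region)
    treated = [s.sample_id for s in samples if s.treatment == "CORT_FLX"]
    control = [s.sample_id for s in samples if s.treatment == "CORT"]
    tables[region] = log_fold_change(study.expression[region], treated, control)

report = regional_concordance(tables["dorsal"], tables["ventral"], alpha=0.05)
print(f"cross-region Pearson r of log2 fold changes: {report.pearson_r_fc:.3f}")
print(f"significant in >=1 region: {report.pct_sig_any:.1f}% of probes")
print(f"significant in both regions: {report.pct_sig_both:.1f}%")
print(f"same direction | significant in >=1 region: {report.pct_same_dir_any:.1f}%")
print(f"same direction | significant in both:       {report.pct_same_dir_both:.1f}%")
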