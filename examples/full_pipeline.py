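"""One-call orchestration of the whole analysis.

Runs every stage — generation, preprocessing, state scoring,
subsampling concordance, connectivity, distance, fold-change
concordance, and behavior association — on a reduced synthetic study
and prints the report's headline numbers.  The same entry point
accepts ``input_mode="files"`` with a directory of TSVs written by
``txstate.write_study`` (or assembled from any expression study in the
documented dialect).
"""

from txstate import GeneratorParams, RunConfig, run_pipeline

config = RunConfig(
    generator_params=GeneratorParams(seed=1, n_probes=2000),
    group_size=400,
    n_groups=5,
    connectivity_max_genes=500,
    exclude_ambiguous=True,
    seed=1,
)
report = run_pipeline(config)
payload = report.to_dict()

for region in ("dorsal", "ventral"):
    sub = payload["subsample_concordance"][region]
    conn = payload["connectivity"][region]
    dist = payload["euclidean_profile"][region]
    print(
        f"{region}: subsample min r = {sub['min_r']:.3f}; "
        f"hierarchy rho = {conn['spearman_connectivity_vs_abs_r']:.2f}; "
        f"distance linearity r = {dist['linearity_r']:.3f}"
    )
conc = payload["regional_concordance"]
print(f"fold-change concordance r = {conc['pearson_r_fc']:.3f}")
for assoc in payload["behavior_associations"]:
    print(f"{assoc['x']} vs {assoc['y']}: {assoc['method']} r = {assoc['r']:+.2f}")
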