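"""End-to-end orchestration of the state analysis.

Stages run in a fixed, recorded order: load or generate -> constant-row
drop -> z-score -> state scores (pooled and per region) -> orientation
-> probe-subsampling concordance -> connectivity (+ state curve) ->
Euclidean distance profile -> per-region fold changes -> cross-region
concordance -> behavior associations.  All randomness flows from a
single root seed expanded into named per-stage seeds, which are logged
and embedded in the report so any stage can be replayed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import behavior_state_report
from .core import ExpressionMatrix, ProbeAnnotation, SampleInfo, ValidationError
from .io import load_expression
from .preprocess import drop_constant_rows, log_fold_change, present_filter, zscore_rows
from .simulate import REGIONS, GeneratorParams, SyntheticStudy, generate_study
from .state import (
    StateScores,
    compute_pca1,
    orient_scores,
    orient_to_treatment,
    partition_probes,
    subsample_state_concordance,
)
from .structure import (
    connectivity_state_curve,
    euclidean_profile,
    gene_connectivity,
    pca1_gene_correlations,
    regional_concordance,
)

logger = logging.getLogger("txstate")

STAGE_ORDER = [
    "input",
    "preprocess",
    "state_scores",
    "subsample_concordance",
    "connectivity",
    "euclidean_profile",
    "fold_changes",
    "regional_concordance",
    "behavior",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``input_mode`` is ``"synthetic"`` (generate from
    ``generator_params``) or ``"files"`` (read the TSV set under
    ``input_dir``).  Alphas: ``fc_alpha`` for fold-change significance,
    ``adjacency_alpha`` for the connectivity network, and
    ``normality_alpha`` for the Pearson/Spearman gate.
    """

    input_mode: str = "synthetic"
    input_dir: str | None = None
    generator_params: GeneratorParams = field(default_factory=GeneratorParams)
    group_size: int = 2000
    n_groups: int | str = 5
    partition_mode: str = "ordered"
    fc_alpha: float = 0.05
    adjacency_alpha: float = 0.001
    normality_alpha: float = 0.05
    connectivity_max_genes: int | None = 2000
    exclude_ambiguous: bool = False
    present_min_fraction: float = 0.5
    seed: int = 1
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fc_alpha", "adjacency_alpha", "normality_alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {value}")
        if self.input_mode not in ("synthetic", "files"):
            raise ValidationError(f"input_mode must be 'synthetic' or 'files'")
        if self.input_mode == "files" and not self.input_dir:
            raise ValidationError("input_mode 'files' requires input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator_params", None)
        config = cls(**raw)
        if gen is not None:
            if "behavior_slopes" in gen:
                gen["behavior_slopes"] = tuple(gen["behavior_slopes"])
            if "behavior_noise" in gen:
                gen["behavior_noise"] = tuple(gen["behavior_noise"])
            config.generator_params = GeneratorParams(**gen)
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator_params"] = self.generator_params.to_dict()
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    config: RunConfig
    stage_seeds: dict[str, int]
    scores: dict[str, StateScores]
    pooled_scores: StateScores
    subsample: dict[str, Any]
    connectivity_summary: dict[str, Any]
    distances: dict[str, Any]
    concordance: dict[str, Any]
    pca1_correlation_summary: dict[str, Any]
    behavior: list[dict]
    counts: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        scores_block = {
            region: {
                "sample_ids": s.sample_ids,
                "pca1": s.pca1.tolist(),
                "variance_explained": s.variance_explained.tolist(),
                "orientation": {k: v for k, v in s.orientation.items()},
            }
            for region, s in self.scores.items()
        }
        return {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "config_hash": self.config.content_hash(),
            "stage_order": STAGE_ORDER,
            "stage_seeds": self.stage_seeds,
            "counts": self.counts,
            "state_scores": scores_block,
            "pooled_scores": {
                "sample_ids": self.pooled_scores.sample_ids,
                "pca1": self.pooled_scores.pca1.tolist(),
                "variance_explained": self.pooled_scores.variance_explained.tolist(),
                "orientation": dict(self.pooled_scores.orientation),
            },
            "subsample_concordance": self.subsample,
            "connectivity": self.connectivity_summary,
            "euclidean_profile": self.distances,
            "regional_concordance": self.concordance,
            "pca1_gene_correlations": self.pca1_correlation_summary,
            "behavior_associations": self.behavior,
        }

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        report_path = directory / "report.json"
        report_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        for name, frame in self.tables.items():
            frame.to_csv(directory / f"{name}.tsv", sep="\t")
        logger.info("wrote report and %d tables to %s", len(self.tables), directory)
        return report_path


def _stage_seeds(root_seed: int) -> dict[str, int]:
    names = ["generator", "partition", "connectivity"]
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _load_inputs(
    config: RunConfig, seeds: dict[str, int]
) -> tuple[dict[str, ExpressionMatrix], list[SampleInfo], ProbeAnnotation]:
    if config.input_mode == "synthetic":
        params = config.generator_params.replace(seed=seeds["generator"])
        study: SyntheticStudy = generate_study(params)
        return dict(study.expression), study.info, study.annotation
    base = Path(config.input_dir)
    from .io import read_present_calls, read_probe_annotation, read_sample_metadata

    info = read_sample_metadata(base / "sample_metadata.tsv")
    expression: dict[str, ExpressionMatrix] = {}
    for region in REGIONS:
        matrix, _, _ = load_expression(
            base / f"expression_{region}.tsv", base / "sample_metadata.tsv"
        )
        expression[region] = matrix

    all_columns = [s.sample_id for s in info]
    probe_index = expression[REGIONS[0]].data.index
    if (base / "present_calls.tsv").exists():
        present = read_present_calls(base / "present_calls.tsv")[all_columns]
    else:
        present = pd.DataFrame(True, index=probe_index, columns=all_columns)
    if (base / "probe_annotation.tsv").exists():
        annotation = read_probe_annotation(base / "probe_annotation.tsv", present)
    else:
        annotation = ProbeAnnotation(
            gene_symbol=pd.Series(pd.NA, index=present.index, dtype="string"),
            present=present,
        )
    return expression, info, annotation


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; see module docstring for the stage
    order.  Any stage failure is re-raised annotated with the stage
    name."""
    seeds = _stage_seeds(config.seed)
    logger.info("stage seeds: %s", seeds)
    stage = "input"
    try:
        expression, info, annotation = _load_inputs(config, seeds)
        by_id = {s.sample_id: s for s in info}
        counts: dict[str, Any] = {}
        tables: dict[str, pd.DataFrame] = {}

        stage = "preprocess"
        z_by_region: dict[str, ExpressionMatrix] = {}
        for region, matrix in expression.items():
            kept = drop_constant_rows(matrix)
            counts[f"constant_probes_dropped_{region}"] = matrix.n_probes - kept.n_probes
            z_by_region[region] = zscore_rows(kept)

        stage = "state_scores"
        scores: dict[str, StateScores] = {}
        for region, z in z_by_region.items():
            raw_scores = compute_pca1(z)
            treated = [s.sample_id for s in info if s.region == region and s.treatment == "CORT_FLX"]
            control = [s.sample_id for s in info if s.region == region and s.treatment == "CORT"]
            if treated and control:
                raw_scores = orient_to_treatment(raw_scores, treated, control)
            scores[region] = raw_scores

        pooled_matrix = ExpressionMatrix(
            pd.concat([expression[r].data for r in expression], axis=1),
            scale_note="pooled regions",
        )
        pooled_z = zscore_rows(drop_constant_rows(pooled_matrix))
        pooled = compute_pca1(pooled_z)
        treated_all = [s.sample_id for s in info if s.treatment == "CORT_FLX"]
        control_all = [s.sample_id for s in info if s.treatment == "CORT"]
        if treated_all and control_all:
            pooled = orient_to_treatment(pooled, treated_all, control_all)
        score_rows = []
        for region, s in scores.items():
            for sid, value in zip(s.sample_ids, s.pca1):
                score_rows.append({"sample_id": sid, "region": region, "pca1": value})
        tables["state_scores"] = pd.DataFrame(score_rows).set_index("sample_id")

        stage = "subsample_concordance"
        subsample_block: dict[str, Any] = {}
        for region, z in z_by_region.items():
            partition = partition_probes(
                z.probe_ids,
                group_size=min(config.group_size, max(2, z.n_probes // 2)),
                n_groups=config.n_groups
                if config.n_groups == "max"
                or config.n_groups * config.group_size <= z.n_probes
                else "max",
                mode=config.partition_mode,
                seed=seeds["partition"],
            )
            report = subsample_state_concordance(z, partition, reference=scores[region])
            subsample_block[region] = report.to_dict()

        stage = "connectivity"
        connectivity_block: dict[str, Any] = {}
        for region, z in z_by_region.items():
            table = gene_connectivity(
                z,
                scores[region],
                alpha=config.adjacency_alpha,
                max_genes=config.connectivity_max_genes,
                seed=seeds["connectivity"],
            )
            curve, rho = connectivity_state_curve(table)
            connectivity_block[region] = {
                "n_genes": table.n_genes,
                "alpha": table.alpha,
                "seed": table.seed,
                "mean_connectivity": float(table.table["connectivity"].mean()),
                "spearman_connectivity_vs_abs_r": rho,
            }
            tables[f"connectivity_{region}"] = table.table
            tables[f"connectivity_curve_{region}"] = curve

        stage = "euclidean_profile"
        distance_block: dict[str, Any] = {}
        for region, z in z_by_region.items():
            profile = euclidean_profile(z, scores[region])
            distance_block[region] = {
                "reference_sample": profile.reference_sample,
                "linearity_r": profile.linearity_r,
            }
            tables[f"distances_{region}"] = profile.as_series().to_frame()

        stage = "fold_changes"
        fc_by_region = {}
        for region, matrix in expression.items():
            treated = [s.sample_id for s in info if s.region == region and s.treatment == "CORT_FLX"]
            control = [s.sample_id for s in info if s.region == region and s.treatment == "CORT"]
            fc_by_region[region] = log_fold_change(matrix, treated, control)
            tables[f"fold_changes_{region}"] = fc_by_region[region].table

        stage = "regional_concordance"
        concordance_block: dict[str, Any] = {}
        if len(fc_by_region) == 2:
            regions = sorted(fc_by_region)
            report = regional_concordance(
                fc_by_region[regions[0]], fc_by_region[regions[1]], alpha=config.fc_alpha
            )
            concordance_block = report.to_dict()

        # PCA1-gene correlation concordance across regions, restricted
        # to probes detected as present in > min_fraction of samples.
        sig_by_region = {}
        for region, z in z_by_region.items():
            present_z = present_filter(z, annotation, config.present_min_fraction)
            corr = pca1_gene_correlations(present_z, scores[region], alpha=config.fc_alpha)
            sig_by_region[region] = corr
        common = sig_by_region[list(sig_by_region)[0]].index
        for corr in sig_by_region.values():
            common = common.intersection(corr.index)
        sig_flags = np.column_stack(
            [sig_by_region[r].loc[common, "significant"].to_numpy() for r in sig_by_region]
        )
        pca1_corr_block = {
            "n_present_probes": int(len(common)),
            "pct_sig_any_region": float(100.0 * sig_flags.any(axis=1).mean()),
            "pct_sig_both_regions": float(100.0 * sig_flags.all(axis=1).mean()),
        }
        counts["present_probes_analyzed"] = int(len(common))

        stage = "behavior"
        behavior_results = behavior_state_report(
            scores,
            info,
            exclude_ambiguous=config.exclude_ambiguous,
            normality_alpha=config.normality_alpha,
        )
        behavior_block = [r.to_dict() for r in behavior_results]
        tables["behavior_associations"] = pd.DataFrame(behavior_block).set_index(["x", "y"])

        report = RunReport(
            config=config,
            stage_seeds=seeds,
            scores=scores,
            pooled_scores=pooled,
            subsample=subsample_block,
            connectivity_summary=connectivity_block,
            distances=distance_block,
            concordance=concordance_block,
            pca1_correlation_summary=pca1_corr_block,
            behavior=behavior_block,
            counts=counts,
            tables=tables,
        )
        if config.output_dir:
            report.write(config.output_dir)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
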