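"""Core data containers for expression-state analysis.

The substrate of every computation is a probes x samples matrix of
log2-scale expression values, together with probe annotation (gene
symbol, per-sample present/absent detection calls) and per-sample
metadata (animal, dentate region, treatment arm, two behavioral
readouts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("txstate")

REGIONS = ("dorsal", "ventral")
TREATMENTS = ("CORT", "CORT_FLX")

#: Ceiling of the novelty-suppressed-feeding latency (8-minute test).
NSF_CEILING_S = 480.0


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class ExpressionMatrix:
    """A probes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    data
        DataFrame indexed by probe ID with one column per sample ID.
        Values must be finite floats on the log2 scale.
    scale_note
        Free text recording the upstream summarization (e.g.
        ``"RMA-like"``, ``"synthetic"``).
    """

    data: pd.DataFrame
    scale_note: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated probe IDs: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample IDs: {dups[:10]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise ValidationError(f"expression matrix contains {n_bad} non-finite values")
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Probes x samples float array (a view onto the frame)."""
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(probe_ids)], scale_note=self.scale_note)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(sample_ids)], scale_note=self.scale_note)


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping plus present/absent detection calls.

    ``gene_symbol`` maps probe ID to gene symbol (NaN/empty when the
    probe has no annotated gene).  ``present`` is a probes x samples
    boolean frame of detection calls; ``present_fraction`` is its row
    mean.
    """

    gene_symbol: pd.Series
    present: pd.DataFrame

    def __post_init__(self) -> None:
        if self.gene_symbol.index.has_duplicates or self.present.index.has_duplicates:
            raise ValidationError("duplicated probe IDs in annotation")
        if not self.gene_symbol.index.equals(self.present.index):
            raise ValidationError("gene_symbol and present tables index different probes")
        self.present = self.present.astype(bool)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.present.index)

    @property
    def present_fraction(self) -> pd.Series:
        return self.present.mean(axis=1)

    def has_gene(self) -> pd.Series:
        """Boolean mask of probes carrying a non-empty gene symbol."""
        sym = self.gene_symbol
        return sym.notna() & (sym.astype(str).str.strip() != "")


@dataclass
class SampleInfo:
    """Metadata for one array: animal, region, treatment, behaviors."""

    sample_id: str
    animal_id: str
    region: str
    treatment: str
    fst_immobility: float
    nsf_latency: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"sample {self.sample_id}: region {self.region!r} not in {REGIONS}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id}: treatment {self.treatment!r} not in {TREATMENTS}"
            )
        if self.fst_immobility < 0:
            raise ValidationError(f"sample {self.sample_id}: negative FST immobility")
        if not 0 <= self.nsf_latency <= NSF_CEILING_S:
            raise ValidationError(
                f"sample {self.sample_id}: NSF latency {self.nsf_latency} outside "
                f"[0, {NSF_CEILING_S}]"
            )


def validate_samples(samples: Iterable[SampleInfo]) -> list[SampleInfo]:
    """Check cross-sample invariants: unique sample IDs and unique
    (animal, region) pairs."""
    samples = list(samples)
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, str]] = set()
    for s in samples:
        if s.sample_id in seen_ids:
            raise ValidationError(f"duplicated sample ID {s.sample_id!r}")
        pair = (s.animal_id, s.region)
        if pair in seen_pairs:
            raise ValidationError(f"duplicated (animal, region) pair {pair}")
        seen_ids.add(s.sample_id)
        seen_pairs.add(pair)
    return samples


def samples_to_frame(samples: Sequence[SampleInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "animal_id": [s.animal_id for s in samples],
            "region": [s.region for s in samples],
            "treatment": [s.treatment for s in samples],
            "fst_immobility_s": [s.fst_immobility for s in samples],
            "nsf_latency_s": [s.nsf_latency for s in samples],
        }
    ).set_index("sample_id", drop=False)


def frame_to_samples(frame: pd.DataFrame) -> list[SampleInfo]:
    required = {
        "sample_id",
        "animal_id",
        "region",
        "treatment",
        "fst_immobility_s",
        "nsf_latency_s",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"sample metadata missing columns: {sorted(missing)}")
    samples = [
        SampleInfo(
            sample_id=str(row.sample_id),
            animal_id=str(row.animal_id),
            region=str(row.region),
            treatment=str(row.treatment),
            fst_immobility=float(row.fst_immobility_s),
            nsf_latency=float(row.nsf_latency_s),
        )
        for row in frame.itertuples(index=False)
    ]
    return validate_samples(samples)


@dataclass
class FoldChangeTable:
    """Per-probe log2 fold changes (treated minus control) with
    two-sided p-values.

    ``table`` has columns ``log2_fc``, ``p_value`` and ``direction``
    (sign of ``log2_fc``), indexed by probe ID.  ``p_value`` is NaN when
    a group had a single sample.
    """

    table: pd.DataFrame
    treated_ids: list[str] = field(default_factory=list)
    control_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("log2_fc", "p_value", "direction"):
            if col not in self.table.columns:
                raise ValidationError(f"fold-change table missing column {col!r}")
        fc = self.table["log2_fc"].to_numpy()
        direction = self.table["direction"].to_numpy()
        if not np.array_equal(np.sign(fc), direction):
            raise ValidationError("direction column must equal sign(log2_fc)")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float = 0.05) -> pd.Series:
        return self.table["p_value"] < alpha
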