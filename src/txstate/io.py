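"""Tab-delimited I/O for expression matrices, present calls and sample
metadata.

File dialects
-------------
Expression matrix
    TSV, header ``probe_id<TAB>sample1<TAB>...``, one probe per row,
    UTF-8, ``.`` decimal, values on the log2 scale.
Present calls
    TSV of the same shape with cells in ``{P, A}`` or ``{1, 0}``.
Sample metadata
    TSV with columns ``sample_id``, ``animal_id``, ``region``,
    ``treatment``, ``fst_immobility_s``, ``nsf_latency_s``.

A reader for GEO series-matrix files (the tab-delimited block between
``!series_matrix_table_begin`` and ``!series_matrix_table_end``) is
provided for applying the pipeline to deposited studies; it yields an
:class:`~txstate.core.ExpressionMatrix` only, since series-matrix
metadata lines are free-form.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleInfo,
    ValidationError,
    frame_to_samples,
    samples_to_frame,
)

logger = logging.getLogger("txstate")

_PRESENT_CODES = {"P": True, "A": False, "1": True, "0": False, "M": False}


def read_expression_matrix(path: str | Path, scale_note: str = "") -> ExpressionMatrix:
    """Read a probes x samples TSV expression matrix.

    Raises :class:`ValidationError` naming the offending cell for
    non-numeric values and the offending probe for duplicated rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path.name}: duplicated probe ID(s): {dups[:10]}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path.name}: non-numeric cell at probe {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iloc[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValidationError(f"{path.name}: missing expression values")
    return ExpressionMatrix(numeric, scale_note=scale_note)


def read_present_calls(path: str | Path) -> pd.DataFrame:
    """Read a present-call TSV (cells in {P,A} or {1,0}) as booleans."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)

    def decode(cell: str) -> bool:
        code = str(cell).strip()
        if code not in _PRESENT_CODES:
            raise ValidationError(f"{path.name}: unrecognized present-call code {cell!r}")
        return _PRESENT_CODES[code]

    return raw.map(decode)


def read_sample_metadata(path: str | Path) -> list[SampleInfo]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("fst_immobility_s", "nsf_latency_s"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col])
    return frame_to_samples(frame)


def read_probe_annotation(path: str | Path, present_calls: pd.DataFrame) -> ProbeAnnotation:
    """Read a probe -> gene symbol TSV (columns ``probe_id``,
    ``gene_symbol``) and combine it with present calls."""
    frame = pd.read_csv(path, sep="\t", dtype=str).set_index("probe_id")
    frame.index = frame.index.astype(str)
    symbols = frame["gene_symbol"].reindex(present_calls.index)
    return ProbeAnnotation(gene_symbol=symbols, present=present_calls)


def load_expression(
    path: str | Path,
    metadata_path: str | Path,
    present_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> tuple[ExpressionMatrix, list[SampleInfo], ProbeAnnotation]:
    """Load and cross-validate an expression study from TSV files.

    The matrix's sample columns are reordered to match the metadata
    order.  Raises an error naming any sample present in the matrix but
    missing from the metadata; metadata rows for samples the matrix
    does not contain (e.g. the other region of a two-region study) are
    ignored with a log line.  When no present-call
    file is given, every probe is treated as present in every sample;
    when no annotation file is given, probes carry no gene symbol.
    """
    matrix = read_expression_matrix(path)
    samples = read_sample_metadata(metadata_path)

    matrix_ids = set(matrix.sample_ids)
    meta_ids = [s.sample_id for s in samples]
    missing_meta = sorted(matrix_ids - set(meta_ids))
    if missing_meta:
        raise ValidationError(
            f"sample(s) in expression matrix but not in metadata: {missing_meta}"
        )
    extra_meta = sorted(set(meta_ids) - matrix_ids)
    if extra_meta:
        # Metadata may cover a whole study while the matrix holds one
        # region; keep only the samples the matrix actually contains.
        logger.info(
            "metadata covers %d sample(s) absent from this matrix; ignoring them",
            len(extra_meta),
        )
        samples = [s for s in samples if s.sample_id in matrix_ids]
        meta_ids = [s.sample_id for s in samples]
    matrix = matrix.subset_samples(meta_ids)

    if present_path is not None:
        present = read_present_calls(present_path)
        if list(present.index) != matrix.probe_ids:
            raise ValidationError("present-call probes do not match expression matrix")
        present = present[meta_ids]
    else:
        present = pd.DataFrame(True, index=matrix.data.index, columns=matrix.data.columns)

    if annotation_path is not None:
        annotation = read_probe_annotation(annotation_path, present)
    else:
        annotation = ProbeAnnotation(
            gene_symbol=pd.Series(pd.NA, index=present.index, dtype="string"),
            present=present,
        )
    return matrix, samples, annotation


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def write_present_calls(present: pd.DataFrame, path: str | Path) -> None:
    coded = present.map(lambda flag: "P" if flag else "A")
    coded.to_csv(path, sep="\t", index_label="probe_id")


def write_sample_metadata(samples: list[SampleInfo], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    frame = pd.DataFrame({"probe_id": annotation.probe_ids})
    frame["gene_symbol"] = annotation.gene_symbol.to_numpy()
    frame.to_csv(path, sep="\t", index=False)


def read_series_matrix(path: str | Path, scale_note: str = "GEO series matrix") -> ExpressionMatrix:
    """Read the expression block of a GEO series-matrix file.

    Only the tab-delimited table between ``!series_matrix_table_begin``
    and ``!series_matrix_table_end`` is parsed.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8", errors="replace").splitlines()
    try:
        start = next(
            i for i, line in enumerate(lines) if line.startswith("!series_matrix_table_begin")
        )
        stop = next(
            i for i, line in enumerate(lines) if line.startswith("!series_matrix_table_end")
        )
    except StopIteration as exc:
        raise ValidationError(f"{path.name}: no series-matrix table block found") from exc
    block = lines[start + 1 : stop]
    if not block:
        raise ValidationError(f"{path.name}: empty series-matrix table block")
    header = [cell.strip('"') for cell in block[0].split("\t")]
    rows = [line.split("\t") for line in block[1:] if line.strip()]
    frame = pd.DataFrame(rows, columns=header).set_index(header[0])
    frame.index = frame.index.map(lambda s: str(s).strip('"'))
    frame = frame.apply(pd.to_numeric)
    logger.info("read series-matrix block: %d probes x %d samples", *frame.shape)
    return ExpressionMatrix(frame, scale_note=scale_note)
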