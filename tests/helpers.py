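"""Small constructors shared across test modules."""

import numpy as np
import pandas as pd

from txstate import ExpressionMatrix, ProbeAnnotation


def make_matrix(values, probe_ids=None, sample_ids=None, **kwargs) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), **kwargs
    )


def make_annotation(
    probe_ids, gene_symbols=None, present_fractions=None, n_samples=4
) -> ProbeAnnotation:
    """Annotation whose present-call rows realize the given fractions
    (fractions must be multiples of 1/n_samples)."""
    probe_ids = list(probe_ids)
    if gene_symbols is None:
        gene_symbols = [f"G{i}" for i in range(len(probe_ids))]
    if present_fractions is None:
        present_fractions = [1.0] * len(probe_ids)
    calls = []
    for frac in present_fractions:
        n_present = round(frac * n_samples)
        assert abs(n_present / n_samples - frac) < 1e-9, "fraction not representable"
        calls.append([True] * n_present + [False] * (n_samples - n_present))
    present = pd.DataFrame(
        calls, index=probe_ids, columns=[f"S{j}" for j in range(n_samples)]
    )
    return ProbeAnnotation(
        gene_symbol=pd.Series(gene_symbols, index=probe_ids, dtype="string"),
        present=present,
    )


def zscore_array(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    return (values - means) / sds
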