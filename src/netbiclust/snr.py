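"""Signal-to-noise ratio of genes over a sample subset.

For one gene g and a sample subset P' the SNR is

    SNR(g, P') = |mu_{g,P'} - mu_{g,P'bar}| / (sigma_{g,P'} + sigma_{g,P'bar})

where P'bar is the complement of P' and sigma is the population standard
deviation.  The absolute value keeps concordant-low (under-expressed) sets
on the same footing as concordant-high ones.  The SNR of a gene set is the
mean over its genes.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np

from .data_io import ExpressionMatrix

__all__ = ["gene_snr", "set_snr", "snr_from_values"]

#: guard against zero denominators on degenerate (constant) sets
_EPS = 1e-12


def snr_from_values(values: np.ndarray, in_mask: np.ndarray) -> float:
    """SNR from one gene's value vector and a boolean in-set mask."""
    n_in = int(in_mask.sum())
    if n_in == 0 or n_in == in_mask.size:
        raise ValueError("sample set must be a proper non-empty subset")
    inside = values[in_mask]
    outside = values[~in_mask]
    dmu = abs(float(inside.mean()) - float(outside.mean()))
    den = float(inside.std(ddof=0)) + float(outside.std(ddof=0))
    if den < _EPS:
        den += _EPS * (1.0 + dmu)
    return dmu / den


def _mask(m: ExpressionMatrix, p_set: Iterable[str]) -> np.ndarray:
    idx = m.sample_indices(p_set)
    mask = np.zeros(m.n_samples, dtype=bool)
    mask[idx] = True
    return mask


def gene_snr(g: str, p_set: Iterable[str], m: ExpressionMatrix) -> float:
    """SNR of gene ``g`` for sample set ``p_set`` against its complement."""
    return snr_from_values(m.gene_values(g), _mask(m, p_set))


def set_snr(genes: Iterable[str], p_set: Iterable[str], m: ExpressionMatrix) -> float:
    """Mean gene-level SNR over a gene set (order-independent)."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    mask = _mask(m, p_set)
    return float(np.mean([snr_from_values(m.gene_values(g), mask) for g in genes]))
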