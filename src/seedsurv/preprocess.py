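"""Normalisation conventions applied before any analysis.

Quantile normalisation forces every sample (column) to share the same value
distribution — the per-rank cross-sample mean — while preserving within-
sample ordering; expression is then logged base 2. Two fold-change baselines
are provided for display: against the sample with the lowest expression of a
gene, and against the median of a panel of normal-tissue pools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io_config import ExpressionMatrix, logger


@dataclass
class FoldChangeVector:
    """Linear-scale fold change of one gene per sample against a baseline."""

    probe_id: str
    sample_ids: list[str]
    fc: np.ndarray
    baseline_desc: str

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        if (self.fc <= 0).any():
            raise ValueError("fold changes must be strictly positive")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise samples so every column shares the per-rank mean
    distribution.

    Ties within a column receive the mean of the rank means they span.
    Requires a complete matrix; impute or drop missing values first.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    if np.isnan(m.values).any():
        raise ValueError(
            "matrix contains missing values; drop or impute them first "
            "(see impute_row_median / read_expression max_missing_frac)"
        )
    x = m.values
    rank_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = rank_means
        # average the assigned rank means over tie groups
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return replace(m, values=out)


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return log2(value + offset) with ``is_log2`` set."""
    shifted = m.values + offset
    bad = np.nanmin(shifted, axis=1) <= 0
    if bad.any():
        names = [m.probe_ids[i] for i in np.flatnonzero(bad)[:10]]
        raise ValueError(f"non-positive values after offset {offset} for probes {names}")
    return replace(m, values=np.log2(shifted), is_log2=True)


def impute_row_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace missing values with the probe's median across samples."""
    x = m.values.copy()
    nan_mask = np.isnan(x)
    if nan_mask.any():
        med = np.nanmedian(x, axis=1)
        x[nan_mask] = np.take(med, np.where(nan_mask)[0])
        logger.info("impute_row_median: imputed %d values", int(nan_mask.sum()))
    return replace(m, values=x)


def _gene_row(m: ExpressionMatrix, gene: str) -> tuple[str, np.ndarray]:
    rows = m.probes_for_gene(gene)
    if len(rows) > 1:
        raise ValueError(f"gene {gene!r} maps to {len(rows)} probes; pass a probe id")
    if rows:
        return m.probe_ids[rows[0]], m.values[rows[0]]
    return gene, m.probe_values(gene)


def fc_vs_min_sample(m: ExpressionMatrix, gene: str) -> FoldChangeVector:
    """Fold change of *gene* in every sample against the sample with its
    lowest expression (the reference, conventionally named T0, has FC 1)."""
    if not m.is_log2:
        raise ValueError("fold-change baselines require log2 expression")
    probe, x = _gene_row(m, gene)
    ref = int(np.argmin(x))
    if (x == x[ref]).sum() > 1:
        logger.info("fc_vs_min_sample: tie for minimum, using first sample %s", m.sample_ids[ref])
    return FoldChangeVector(
        probe_id=probe,
        sample_ids=list(m.sample_ids),
        fc=2.0 ** (x - x[ref]),
        baseline_desc=f"lowest-expression sample {m.sample_ids[ref]}",
    )


def fc_vs_normal_pool(m: ExpressionMatrix, gene: str, normal_sample_ids: list[str]) -> FoldChangeVector:
    """Fold change against the median expression over normal-tissue pools."""
    if not m.is_log2:
        raise ValueError("fold-change baselines require log2 expression")
    if not normal_sample_ids:
        raise ValueError("normal_sample_ids must be non-empty")
    probe, x = _gene_row(m, gene)
    idx = [m.sample_ids.index(s) for s in normal_sample_ids]
    baseline = float(np.median(x[idx]))
    return FoldChangeVector(
        probe_id=probe,
        sample_ids=list(m.sample_ids),
        fc=2.0 ** (x - baseline),
        baseline_desc=f"median of {len(idx)} normal pools",
    )
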