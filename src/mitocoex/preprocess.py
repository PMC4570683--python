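"""Detection filtering and normalization of the RPKM matrix.

Pipeline order: ``filter_detected`` (drop genes not measured in enough
samples) → ``log_transform`` (log2 of RPKM plus a pseudocount) →
``median_center`` (divide each gene's log profile by its own median so the
per-gene median is exactly 1.0, a fold-like quantity around the gene's
typical level).  Mitochondrial genes are normalized the same way as nuclear
genes; the origin flag is carried through every step so the matrix can be
partitioned losslessly afterwards.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


def filter_detected(matrix: ExpressionMatrix, min_samples: int | None = None) -> ExpressionMatrix:
    """Retain genes with RPKM > 0 in at least ``min_samples`` samples.

    ``min_samples=None`` requires detection in every sample.  Raises if no
    gene survives.
    """
    if matrix.state != "raw":
        raise NormalizationError("detection filtering applies to the raw RPKM state")
    if min_samples is None:
        min_samples = matrix.n_samples
    if not 0 < min_samples <= matrix.n_samples:
        raise ValueError(f"min_samples must be in [1, {matrix.n_samples}]")
    detected = (matrix.values() > 0).sum(axis=1) >= min_samples
    if not detected.any():
        raise NormalizationError("no genes retained by the detection filter")
    kept = matrix.data.index[detected]
    logger.info("detection filter retained %d/%d genes", detected.sum(), matrix.n_genes)
    return matrix.subset_genes(kept)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0,
                  base: float = 2.0) -> ExpressionMatrix:
    """log_base(RPKM + pseudocount); pseudocount 0 requires all values > 0."""
    if matrix.state != "raw":
        raise NormalizationError("log transform applies to the raw RPKM state")
    if pseudocount < 0:
        raise ValueError("pseudocount must be ≥ 0")
    values = matrix.values()
    if pseudocount == 0 and (values <= 0).any():
        g, s = np.argwhere(values <= 0)[0]
        raise NormalizationError(
            f"zero/negative RPKM at gene {matrix.gene_ids[g]!r}, sample "
            f"{matrix.sample_ids[s]!r}; a positive pseudocount is required"
        )
    logged = np.log(values + pseudocount) / np.log(base)
    return matrix.with_data(
        matrix.data.__class__(logged, index=matrix.data.index, columns=matrix.data.columns),
        state="log",
    )


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene's profile by its median so the median is 1.0.

    Genes whose log-median is ≤ 0 cannot be centered multiplicatively
    without flipping the profile's sign; they are dropped with a warning.
    Centering an already-centered matrix is a no-op (every median is 1).
    """
    if matrix.state not in ("log", "centered"):
        raise NormalizationError("median centering applies to the log state")
    values = matrix.values()
    medians = np.median(values, axis=1)
    keep = medians > 0
    if not keep.all():
        dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
        logger.warning(
            "dropping %d gene(s) with non-positive log-median: %s",
            len(dropped), dropped[:5],
        )
        values, medians = values[keep], medians[keep]
    if values.shape[0] == 0:
        raise NormalizationError("no genes with positive log-median to center")
    centered = values / medians[:, None]
    kept_index = matrix.data.index[keep]
    return matrix.with_data(
        matrix.data.__class__(centered, index=kept_index, columns=matrix.data.columns),
        state="centered",
    )


def normalize(matrix: ExpressionMatrix, min_samples: int | None = None,
              pseudocount: float = 1.0, base: float = 2.0) -> ExpressionMatrix:
    """filter_detected → log_transform → median_center in one call."""
    return median_center(log_transform(filter_detected(matrix, min_samples),
                                       pseudocount, base))
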