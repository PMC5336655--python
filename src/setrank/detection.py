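"""Detection calling on expression matrices.

Enrichment results can reflect the tissue a sample came from rather
than the tested condition when the background universe contains genes
the tissue never expresses.  For technologies without an absolute
presence call (DNA microarrays), transcripts that were never detected
are identified by their signature of *both* low variability and low
intensity: the relative median absolute deviation (rMAD = MAD / mean,
on non-log intensities) below the median rMAD, combined with a log-mean
intensity below the 5th percentile of the log-means of the variable
(high-rMAD) probesets.  The detected rows form a sample-source-bias
free background set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def rmad(row) -> float:
    """Relative median absolute deviation: MAD / mean.

    Computed on non-log intensities; the MAD is raw (no 1.4826
    consistency scaling).  The mean must be positive.
    """
    x = np.asarray(row, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity vector")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("row mean must be positive for rMAD")
    mad = np.median(np.abs(x - np.median(x)))
    return float(mad / mean)


@dataclass
class DetectionCallResult:
    """Per-row detection flags with the two data-driven cutoffs."""

    rmad_cutoff: float
    mean_cutoff: float
    detected: pd.Series  # boolean, indexed by row ID
    rmads: pd.Series
    log_means: pd.Series

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    @property
    def n_undetected(self) -> int:
        return int((~self.detected).sum())

    def detected_rows(self) -> list:
        return self.detected.index[self.detected].tolist()


def detection_call(matrix: pd.DataFrame) -> DetectionCallResult:
    """Flag undetected rows of a non-log expression matrix.

    Two cutoffs are derived from the data: the median of all row rMADs,
    and the 5th percentile (linear interpolation) of the log2-mean
    intensity among rows with rMAD *above* the median.  A row is
    undetected iff its rMAD and log2-mean both fall strictly below
    their respective cutoffs; all other rows are detected.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("expression matrix needs >= 2 rows and >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression intensities must be non-negative")
    means = values.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("every row must have positive mean intensity")
    mads = np.median(np.abs(values - np.median(values, axis=1, keepdims=True)),
                     axis=1)
    rmads = mads / means
    # log2 of per-sample intensities, then row mean; zeros are floored at
    # the smallest positive value in the matrix to keep the log finite.
    positive_min = values[values > 0].min()
    log_means = np.log2(np.maximum(values, positive_min)).mean(axis=1)

    rmad_cutoff = float(np.median(rmads))
    high_rmad = rmads > rmad_cutoff
    if not high_rmad.any():
        # All-constant (or all-equal-rMAD) matrix: degenerate cutoffs.
        import warnings
        warnings.warn("degenerate rMAD distribution: no rows above the "
                      "median rMAD; all rows called detected")
        mean_cutoff = -np.inf
    else:
        mean_cutoff = float(np.percentile(log_means[high_rmad], 5))

    undetected = (rmads < rmad_cutoff) & (log_means < mean_cutoff)
    return DetectionCallResult(
        rmad_cutoff=rmad_cutoff,
        mean_cutoff=mean_cutoff,
        detected=pd.Series(~undetected, index=matrix.index),
        rmads=pd.Series(rmads, index=matrix.index),
        log_means=pd.Series(log_means, index=matrix.index),
    )


def build_background(source, row_to_gene=None) -> frozenset:
    """Background gene universe from detected rows or an explicit list.

    ``source`` is either a non-log expression matrix (detection calling
    is run and the detected rows' genes form the background), an
    already-computed :class:`DetectionCallResult`, or an iterable of
    gene IDs taken verbatim.  ``row_to_gene`` optionally maps row IDs
    (probesets) to gene IDs; a gene is in the background if *any* of
    its rows is detected.
    """
    if isinstance(source, pd.DataFrame):
        source = detection_call(source)
    if isinstance(source, DetectionCallResult):
        rows = source.detected_rows()
        if row_to_gene is not None:
            genes = frozenset(row_to_gene[r] for r in rows if r in row_to_gene)
        else:
            genes = frozenset(rows)
    else:
        genes = frozenset(source)
    if not genes:
        raise ValueError("background set is empty")
    return genes


def read_expression_matrix(path, sep=None) -> pd.DataFrame:
    """Read a rows-by-samples intensity matrix (TSV/CSV, header row)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)
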