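"""Isoform quantification table parsing and expressed-isoform calls.

The quantification table is tab-separated: a header row, a transcript-ID
first column and one numeric abundance column per sample (TPM by
convention, but units are treated as opaque non-negative abundances).
Per-gene classification uses a linear-interpolation quantile over the
gene's isoform mean abundances; an isoform is expressed iff its mean is
strictly greater than the cutoff.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import strip_version

logger = logging.getLogger(__name__)

__all__ = ["ExpressionTable", "ExpressionCall", "parse_quant_table", "classify_expressed"]


@dataclass
class ExpressionCall:
    transcript_id: str
    mean_tpm: float
    expressed: bool
    gene_quantile_cutoff: float


class ExpressionTable:
    """Per-transcript abundances across samples with derived means."""

    def __init__(self, frame: pd.DataFrame, aggregate: str = "mean"):
        if frame.empty:
            raise ValueError("empty expression table")
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript IDs in expression table: {dupes}")
        values = frame.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression table contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression table contains negative values")
        self.frame = frame
        if aggregate == "mean":
            agg = frame.mean(axis=1)
        elif aggregate == "median":
            agg = frame.median(axis=1)
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        self._mean = dict(zip((strip_version(i) for i in frame.index), agg.to_numpy(dtype=float)))

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.frame.index)

    def mean_tpm(self, transcript_id: str) -> float:
        """Mean abundance for a transcript; 0.0 (with a warning) if absent."""
        key = strip_version(transcript_id)
        if key not in self._mean:
            logger.warning("transcript %s absent from expression table; assuming 0", transcript_id)
            return 0.0
        return self._mean[key]

    def __contains__(self, transcript_id: str) -> bool:
        return strip_version(transcript_id) in self._mean


def parse_quant_table(source, aggregate: str = "mean") -> ExpressionTable:
    """Load a tab-separated quantification table.

    ``source`` may be a path, a file object, or the table text itself.
    The first column holds transcript IDs; all remaining columns must be
    numeric. Non-numeric cells raise with the offending row and column.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep="\t", index_col=0, dtype=str)
    if frame.empty or frame.shape[1] == 0:
        raise ValueError("expression table has no sample columns or no rows")
    numeric = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric value in expression table at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = frame.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"missing value in expression table at row {row!r}, column {col!r}")
        numeric[col] = converted.astype(float)
    return ExpressionTable(numeric, aggregate=aggregate)


def classify_expressed(
    mean_tpms: dict[str, float],
    threshold_percentile: float = 75.0,
    cutoff: float | None = None,
) -> list[ExpressionCall]:
    """Classify one gene's isoforms as expressed via a quantile cutoff.

    The cutoff is the linear-interpolation percentile (index
    ``h = p/100 * (n-1)`` between order statistics) of the gene's isoform
    means; an isoform is expressed iff its mean is strictly greater.
    Degenerate cases: if every isoform is 0 the gene is unexpressed
    (all calls False); if the strict comparison leaves nothing expressed
    but total expression is positive, every positive isoform is marked
    expressed instead, so quantifiably expressed genes stay designable.

    Passing an explicit ``cutoff`` (e.g. a table-wide global quantile)
    bypasses the per-gene percentile computation.
    """
    if not mean_tpms:
        raise ValueError("no isoforms supplied")
    if not 0 <= threshold_percentile <= 100:
        raise ValueError(f"threshold percentile {threshold_percentile} outside [0,100]")
    ids = list(mean_tpms)
    values = np.asarray([mean_tpms[i] for i in ids], dtype=float)
    if cutoff is None:
        cutoff = float(np.percentile(values, threshold_percentile))
    expressed = values > cutoff
    if not expressed.any():
        if values.sum() > 0:
            expressed = values > 0  # degenerate distribution fallback
        else:
            logger.warning("gene with all-zero expression: flagged not expressed")
    return [
        ExpressionCall(
            transcript_id=tid,
            mean_tpm=float(v),
            expressed=bool(e),
            gene_quantile_cutoff=cutoff,
        )
        for tid, v, e in zip(ids, values, expressed)
    ]
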