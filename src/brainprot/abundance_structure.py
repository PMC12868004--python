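"""Per-region cumulative-abundance quartile partitioning.

Within each region, proteins are ranked by their share of the region's
total mean ppm abundance; the descending cumulative curve is cut at the
configured bounds (25/50/75/100% by default), so Q1 holds the most abundant
proteins that together make up the first quarter of the region's signal.
A protein straddling a cut is assigned by the start of its own cumulative
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import logging

import numpy as np
import pandas as pd

from .dataio import (
    AbundanceMatrix,
    AnalysisConfig,
    Region,
    SampleAnnotation,
    ValidationError,
    annotations_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["region_relative_abundance", "cumulative_quartiles", "quartile_tables", "QuartileTable"]


def region_relative_abundance(
    matrix: AbundanceMatrix, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Per-region relative-abundance fractions (proteins x regions).

    For each region: the mean linear ppm per protein over its observed
    samples, divided by the region total, so the column sums to 1.
    Proteins unobserved in a region are NaN; a region without samples is
    skipped with a warning.
    """
    if matrix.stage != "ppm":
        raise ValidationError(f"expects stage ppm, got {matrix.stage!r}")
    ann = annotations_to_frame(annotations)
    missing = [s for s in matrix.sample_ids if s not in ann.index]
    if missing:
        raise ValidationError(f"samples not present in annotations: {missing[:5]}")
    region_of = ann.loc[matrix.sample_ids, "region"]
    out = {}
    for region in Region:
        cols = [s for s in matrix.sample_ids if region_of[s] == region.value]
        if not cols:
            if (ann["region"] == region.value).any():  # pragma: no cover
                logger.warning("region %s has no samples in matrix; skipped", region.value)
            continue
        mean = matrix.values[cols].mean(axis=1, skipna=True)
        out[region.value] = mean / mean.sum(skipna=True)
    return pd.DataFrame(out, index=matrix.protein_ids)


@dataclass
class QuartileTable:
    """One region's partition: per-protein assignment and per-bin counts."""

    assignments: pd.DataFrame  # protein_id, fraction, cum_start, quartile
    counts: pd.Series  # quartile label -> protein count


def cumulative_quartiles(
    fractions: pd.Series, bounds: Sequence[float] = (0.25, 0.50, 0.75, 1.00)
) -> QuartileTable:
    """Partition one region's fraction vector into cumulative-abundance bins.

    Fractions are sorted descending (ties by protein_id), the cumulative
    start of protein i is the summed fraction of everything ranked before
    it, and its bin is the interval [b_{k-1}, b_k) containing that start.
    """
    vals = fractions.dropna()
    if (vals < 0).any():
        raise ValidationError("fractions must be nonnegative")
    total = float(vals.sum())
    if vals.empty or not np.isclose(total, 1.0, atol=1e-9):
        raise ValidationError(f"fractions must sum to 1 (got {total})")
    bounds = tuple(float(b) for b in bounds)
    order = pd.DataFrame({"fraction": vals})
    order.index.name = "protein_id"
    order = order.sort_values(
        ["fraction", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index()
    cum_start = np.concatenate([[0.0], order["fraction"].to_numpy()[:-1].cumsum()])
    labels = [f"Q{k + 1}" for k in range(len(bounds))]
    bin_idx = np.searchsorted(bounds, cum_start, side="right")
    bin_idx = np.minimum(bin_idx, len(bounds) - 1)  # numeric guard at the top edge
    order["cum_start"] = cum_start
    order["quartile"] = [labels[i] for i in bin_idx]
    counts = order["quartile"].value_counts().reindex(labels, fill_value=0)
    counts.name = "n_proteins"
    return QuartileTable(assignments=order, counts=counts)


def quartile_tables(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quartile partition for every region.

    Returns a long assignment table (region, protein_id, fraction,
    cum_start, quartile) and a counts table (region x quartile).
    """
    fractions = region_relative_abundance(matrix, annotations)
    assign_rows, count_rows = [], []
    for region in fractions.columns:
        table = cumulative_quartiles(fractions[region], config.quartile_bounds)
        block = table.assignments.copy()
        block.insert(0, "region", region)
        assign_rows.append(block)
        row = {"region": region}
        row.update(table.counts.to_dict())
        count_rows.append(row)
    return (
        pd.concat(assign_rows, ignore_index=True),
        pd.DataFrame(count_rows),
    )
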