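"""ppm normalization, log2 transform, QC summaries and complete-case PCA.

Normalization scales each sample's observed intensities to parts-per-million
of that sample's observed total (sum over observed proteins only), making
samples of different acquisition depth comparable; the log2 transform then
puts abundances on the scale the downstream ANOVA assumes.  Missing values
propagate untouched: there is no pseudocount and no imputation anywhere, so
each downstream statistic defines its own complete-data requirement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataio import (
    AbundanceMatrix,
    Region,
    SampleAnnotation,
    ValidationError,
    annotations_to_frame,
)

__all__ = ["to_ppm", "log2_transform", "qc_report", "pca_scores", "QcReport", "PcaResult"]

PPM_SCALE = 1e6


def to_ppm(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its observed values sum to 10^6 (ppm).

    Accepts a raw matrix (the normal path) or an already-normalized ppm
    matrix, on which the operation is the identity up to rounding.
    """
    if matrix.stage not in ("raw", "ppm"):
        raise ValidationError(f"to_ppm expects stage raw or ppm, got {matrix.stage!r}")
    totals = matrix.values.sum(axis=0, skipna=True)
    empty = totals[matrix.values.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValidationError(f"samples with no observed values: {list(empty.index)}")
    values = matrix.values.div(totals, axis=1) * PPM_SCALE
    return AbundanceMatrix(values=values, stage="ppm")


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of a ppm matrix; missing values stay missing."""
    if matrix.stage != "ppm":
        raise ValidationError(f"log2_transform expects stage ppm, got {matrix.stage!r}")
    return AbundanceMatrix(values=np.log2(matrix.values), stage="log2ppm")


def normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convenience composition: raw -> ppm -> log2ppm."""
    return log2_transform(to_ppm(matrix))


@dataclass
class QcReport:
    """Quality-control summaries of a raw/ppm matrix pair.

    samples : per sample raw total and observed-protein count.
    proteins : per protein missing fraction.
    protein_region_cv : coefficient of variation of linear ppm per
        (protein, region), NaN where fewer than two observations exist.
    regions : identified-protein count (observed in >=1 sample) and the
        log10 dynamic range of observed ppm values per region.
    median_missing_fraction : median of the per-protein missing fractions,
        the headline completeness statistic.
    """

    samples: pd.DataFrame
    proteins: pd.DataFrame
    protein_region_cv: pd.DataFrame
    regions: pd.DataFrame
    median_missing_fraction: float


def qc_report(
    raw: AbundanceMatrix,
    ppm: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
) -> QcReport:
    if raw.stage != "raw" or ppm.stage != "ppm":
        raise ValidationError("qc_report expects a (raw, ppm) matrix pair")
    ann = annotations_to_frame(annotations)
    missing = [s for s in raw.sample_ids if s not in ann.index]
    if missing or raw.sample_ids != ppm.sample_ids:
        raise ValidationError(f"annotation/sample mismatch: {missing[:5]}")

    samples = pd.DataFrame(
        {
            "sample_id": raw.sample_ids,
            "raw_total": raw.values.sum(axis=0, skipna=True).to_numpy(),
            "n_observed": raw.values.notna().sum(axis=0).to_numpy(),
        }
    )
    miss_frac = raw.values.isna().mean(axis=1)
    proteins = pd.DataFrame(
        {"protein_id": raw.protein_ids, "missing_fraction": miss_frac.to_numpy()}
    )

    region_of = ann["region"]
    cv_cols: dict[str, np.ndarray] = {}
    region_rows = []
    for region in Region:
        cols = [s for s in ppm.sample_ids if region_of[s] == region.value]
        if not cols:
            continue
        block = ppm.values[cols]
        n_obs = block.notna().sum(axis=1)
        mean = block.mean(axis=1, skipna=True)
        sd = block.std(axis=1, ddof=1, skipna=True)
        cv = (sd / mean).where(n_obs >= 2)
        cv_cols[region.value] = cv.to_numpy()
        observed = block.to_numpy()[~np.isnan(block.to_numpy())]
        region_rows.append(
            {
                "region": region.value,
                "n_samples": len(cols),
                "n_identified": int((n_obs >= 1).sum()),
                "dynamic_range_log10": float(np.log10(observed.max() / observed.min()))
                if observed.size
                else np.nan,
            }
        )
    protein_region_cv = pd.DataFrame(cv_cols, index=ppm.protein_ids)
    protein_region_cv.index.name = "protein_id"
    regions = pd.DataFrame(region_rows)
    return QcReport(
        samples=samples,
        proteins=proteins,
        protein_region_cv=protein_region_cv,
        regions=regions,
        median_missing_fraction=float(miss_frac.median()),
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def pca_scores(matrix: AbundanceMatrix, n_components: int = 2) -> PcaResult:
    """Complete-case PCA of samples on the log2-ppm matrix.

    Proteins with any missing value are dropped (imputation would inject
    structure the analysis never specifies); each retained protein is
    centered across samples and sample scores are projections onto the top
    right-singular directions.
    """
    if matrix.stage != "log2ppm":
        raise ValidationError(f"pca_scores expects stage log2ppm, got {matrix.stage!r}")
    complete = matrix.values.dropna(axis=0, how="any")
    if len(complete) < 2:
        raise ValidationError(
            "fewer than 2 proteins observed in every sample; imputation is out "
            "of scope, so PCA requires complete proteins"
        )
    data = complete.to_numpy().T  # samples x proteins
    if n_components > min(data.shape):
        raise ValidationError("n_components exceeds the data dimensions")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    frame = pd.DataFrame(
        scores,
        index=complete.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    frame.index.name = "sample_id"
    return PcaResult(scores=frame, explained_variance_ratio=pca.explained_variance_ratio_)
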