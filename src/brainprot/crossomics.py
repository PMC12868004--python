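"""RNA region-specificity calling and proteome-transcriptome concordance.

The RNA side follows the consensus-transcriptomics convention: nTPM values
below a floor (1 by default) are treated as not expressed; the remaining
values are log2 transformed, and a gene is region-specific when its maximum
log2 nTPM is at least ``rna_ratio`` (2 by default) times the mean log2 nTPM
of the remaining non-missing regions.  Note this is a ratio of log-values,
exactly as the rule is stated, not a fold change; the boundary is
non-strict.  When the remaining regions' mean is zero (or no remaining
region is expressed), the limit convention applies: specific iff the
maximum log2 value is positive.

Protein-side calls are translated into the coarser RNA region vocabulary
(the four lobes and OB/OT collapse onto cortex) and each protein is
classified as detected by both omics, by proteomics only, by
transcriptomics only, as background, or as unmapped when it has no gene.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import AnalysisConfig, Region, RnaTable, ValidationError
from .synthetic_data import DEFAULT_PROTEIN_TO_RNA

__all__ = [
    "rna_specificity",
    "map_protein_regions_to_rna",
    "concordance_classify",
    "CONCORDANCE_CLASSES",
]

CONCORDANCE_CLASSES = ("both", "protein_only", "rna_only", "unmapped", "background")


def rna_specificity(
    rna: RnaTable, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Region-specificity call per gene.

    Returns one row per gene: max_region (first label on ties), max_log2,
    mean_rest_log2 (NaN when no remaining region is expressed), n_rest and
    the specific flag.
    """
    if rna.ntpm.shape[1] < 2:
        raise ValidationError("need >=2 regions for RNA specificity")
    vals = rna.ntpm.to_numpy(dtype=float)
    vals = np.where(vals < config.rna_lower, np.nan, vals)
    with np.errstate(invalid="ignore"):
        log2 = np.log2(vals)

    present = ~np.isnan(log2)
    any_present = present.any(axis=1)
    masked = np.where(present, log2, -np.inf)
    max_pos = masked.argmax(axis=1)
    rows = np.arange(len(log2))
    max_log2 = np.where(any_present, masked[rows, max_pos], np.nan)

    rest = log2.copy()
    rest[rows, max_pos] = np.nan
    rest_present = ~np.isnan(rest)
    n_rest = rest_present.sum(axis=1)
    rest_sum = np.where(rest_present, rest, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_rest = np.where(n_rest > 0, rest_sum / np.maximum(n_rest, 1), np.nan)

    specific = np.zeros(len(log2), dtype=bool)
    has_max = any_present
    rest_zero = has_max & ((n_rest == 0) | (np.nan_to_num(mean_rest) == 0))
    specific[rest_zero] = max_log2[rest_zero] > 0
    ratio_case = has_max & (n_rest > 0) & (np.nan_to_num(mean_rest) > 0)
    specific[ratio_case] = (
        max_log2[ratio_case] >= config.rna_ratio * mean_rest[ratio_case]
    )

    labels = np.array(rna.region_labels, dtype=object)
    return pd.DataFrame(
        {
            "gene_id": rna.gene_ids,
            "max_region": pd.array(
                [labels[i] if ok else None for i, ok in zip(max_pos, any_present)],
                dtype="string",
            ),
            "max_log2": max_log2,
            "mean_rest_log2": mean_rest,
            "n_rest": n_rest,
            "specific": specific,
        }
    )


def map_protein_regions_to_rna(
    spec_table: pd.DataFrame,
    region_map: Mapping[Region, str | None] = DEFAULT_PROTEIN_TO_RNA,
) -> pd.DataFrame:
    """Translate protein-side calls into the RNA region vocabulary.

    Returns one row per protein of the specificity table: the call flag,
    the mapped RNA-side region for called proteins (NA when the protein's
    region has no RNA counterpart, flagged ``unmappable``).  A called
    protein whose region is absent from the map altogether is an error.
    """
    tokens = {r.value: label for r, label in region_map.items()}
    rows = []
    for row in spec_table.itertuples():
        called = bool(row.call)
        rna_region = None
        unmappable = False
        if called:
            region = str(row.max_region)
            if region not in tokens:
                raise ValidationError(
                    f"region map lacks an entry for called region {region!r}"
                )
            rna_region = tokens[region]
            unmappable = rna_region is None
        rows.append(
            {
                "protein_id": row.protein_id,
                "call": called,
                "rna_region": rna_region,
                "unmappable": unmappable,
            }
        )
    out = pd.DataFrame(rows)
    out["rna_region"] = out["rna_region"].astype("string")
    return out


def concordance_classify(
    protein_calls: pd.DataFrame,
    rna_calls: pd.DataFrame,
    id_map: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-omics class per protein.

    Classes partition the protein universe: ``unmapped`` (no gene),
    ``both`` (protein called and gene RNA-specific; region_agreement
    records whether the mapped regions coincide), ``protein_only``,
    ``rna_only`` and ``background``.  ``both`` does not require region
    agreement; the flag is reported separately.
    """
    if id_map["protein_id"].duplicated().any():
        dupes = id_map.loc[id_map["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValidationError(f"protein mapped to more than one gene: {dupes}")
    gene_of = dict(zip(id_map["protein_id"], id_map["gene_id"]))
    rna_by_gene = rna_calls.set_index("gene_id")

    rows = []
    for row in protein_calls.itertuples():
        gene = gene_of.get(row.protein_id)
        agreement: bool | None = None
        if gene is None or gene not in rna_by_gene.index:
            cls = "unmapped"
        else:
            gene_specific = bool(rna_by_gene.loc[gene, "specific"])
            if row.call and gene_specific:
                cls = "both"
                rna_region = row.rna_region
                agreement = (
                    rna_region is not None
                    and not pd.isna(rna_region)
                    and str(rna_region) == str(rna_by_gene.loc[gene, "max_region"])
                )
            elif row.call:
                cls = "protein_only"
            elif gene_specific:
                cls = "rna_only"
            else:
                cls = "background"
        rows.append(
            {
                "protein_id": row.protein_id,
                "gene_id": gene,
                "class": cls,
                "region_agreement": agreement,
            }
        )
    out = pd.DataFrame(rows)
    out["gene_id"] = out["gene_id"].astype("string")
    return out
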