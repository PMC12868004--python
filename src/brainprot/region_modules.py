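"""Region-region correlation, complete-linkage clustering, and comparison
with the observed three-group structure of the regional proteome.

Regions are summarized by their mean log2-ppm profile across proteins;
pairwise Pearson correlations between profiles (pairwise-complete over
shared proteins) feed a complete-linkage agglomeration on the correlation
distance d = 1 - r.  The observed grouping this analysis recovers consists
of the four cortical lobes, the hippocampus-amygdala pair, and the
thalamus/hypothalamus-corpus callosum-ventricles core.  (The wider
three-module framework additionally places THA/HT in the limbic-relay
network and OC on the midline axis; a dendrogram cut cannot express
overlapping membership, so the comparison constants here are the disjoint
co-clustering groups.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import (
    AbundanceMatrix,
    AnalysisConfig,
    CORTICAL_LOBES,
    Region,
    SampleAnnotation,
    ValidationError,
)
from .specificity import region_stats

__all__ = [
    "FRAMEWORK_GROUPS",
    "RegionCorrelationMatrix",
    "Dendrogram",
    "FrameworkComparison",
    "region_profile_matrix",
    "region_correlation",
    "hierarchical_cluster",
    "compare_to_framework",
]

#: Expected co-clustering groups at the k=4 cut.
FRAMEWORK_GROUPS: dict[str, tuple[Region, ...]] = {
    "cortical_lobes": CORTICAL_LOBES,
    "limbic_pair": (Region.HIP, Region.AN),
    "midline_core": (Region.THA_HT, Region.CC, Region.VT),
}


def region_profile_matrix(
    matrix: AbundanceMatrix, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Proteins x regions mean log2-ppm profiles (NaN where unobserved)."""
    stats = region_stats(matrix, annotations)
    if stats.means.shape[1] < 2:
        raise ValidationError("need >=2 regions to build profiles")
    return stats.means


@dataclass
class RegionCorrelationMatrix:
    r: pd.DataFrame  # regions x regions Pearson coefficients
    n_pairs: pd.DataFrame  # proteins shared per region pair


def region_correlation(profiles: pd.DataFrame) -> RegionCorrelationMatrix:
    """Pairwise-complete Pearson correlation between region profiles.

    Each region pair is correlated over the proteins with both means
    present; the pair counts are recorded so the pairwise-complete choice
    is auditable.  A pair sharing fewer than 3 proteins is an error.
    """
    mask = profiles.notna().astype(int)
    n_pairs = mask.T @ mask
    off = ~np.eye(len(n_pairs), dtype=bool)
    if (n_pairs.to_numpy()[off] < 3).any():
        bad = np.argwhere((n_pairs.to_numpy() < 3) & off)[0]
        raise ValidationError(
            f"region pair ({n_pairs.index[bad[0]]}, {n_pairs.columns[bad[1]]}) "
            f"shares fewer than 3 proteins"
        )
    r = profiles.corr(method="pearson")
    np.fill_diagonal(r.to_numpy(), 1.0)
    return RegionCorrelationMatrix(r=r, n_pairs=n_pairs)


@dataclass
class Dendrogram:
    """Agglomeration record in scipy convention.

    Leaves are 0..n-1 in ``leaves`` order; merge i creates cluster n+i.
    ``merges`` rows are (cluster_a, cluster_b, height).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def cut(self, k: int) -> list[set[str]]:
        """Flat clusters after keeping the first n-k merges."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValidationError(f"cut count k={k} outside [1, {n}]")
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for i, (a, b, _) in enumerate(self.merges[: n - k]):
            members[n + i] = members.pop(a) | members.pop(b)
        return [
            {self.leaves[i] for i in group} for group in members.values()
        ]


def hierarchical_cluster(
    corr: RegionCorrelationMatrix, config: AnalysisConfig = AnalysisConfig()
) -> Dendrogram:
    """Complete-linkage agglomeration on the correlation distance 1 - r.

    Ties in the minimum inter-cluster distance are broken by the smallest
    (cluster_a, cluster_b) index pair, so the merge order is deterministic
    and invariant to input perturbations below the tie tolerance.
    """
    labels = list(corr.r.columns)
    dist = 1.0 - corr.r.to_numpy(dtype=float)
    n = len(labels)
    active: dict[int, set[int]] = {i: {i} for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        ids = sorted(active)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = max(dist[x, y] for x in active[a] for y in active[b])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, float(d)))
        active[next_id] = active.pop(a) | active.pop(b)
        next_id += 1
    return Dendrogram(leaves=labels, merges=merges)


@dataclass
class FrameworkComparison:
    """Co-clustering flags for the expected region groups at a cut.

    ``co_clustered`` maps group name -> True/False, or None when a member
    region is absent from the dendrogram leaves.
    """

    k: int
    co_clustered: dict[str, bool | None]

    @property
    def n_recovered(self) -> int:
        return sum(1 for v in self.co_clustered.values() if v)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": name,
                "members": "|".join(r.value for r in FRAMEWORK_GROUPS[name]),
                "co_clustered": "NA" if flag is None else flag,
            }
            for name, flag in self.co_clustered.items()
        ]
        return pd.DataFrame(rows)


def compare_to_framework(
    dend: Dendrogram,
    k: int = 4,
    groups: Mapping[str, tuple[Region, ...]] = FRAMEWORK_GROUPS,
) -> FrameworkComparison:
    """Cut the dendrogram into k clusters and flag each expected group
    co-clustered iff all its members land in one cluster."""
    clusters = dend.cut(k)
    leaf_set = set(dend.leaves)
    flags: dict[str, bool | None] = {}
    for name, members in groups.items():
        tokens = {r.value for r in members}
        if not tokens <= leaf_set:
            flags[name] = None
            continue
        flags[name] = any(tokens <= cluster for cluster in clusters)
    return FrameworkComparison(k=k, co_clustered=flags)
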