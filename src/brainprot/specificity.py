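"""Region-specific protein calling: donor-blocked ANOVA with consensus
intra-donor correlation, BH adjustment and the fold-change rule.

The calling rule declares a protein region-specific when (i) its region of
highest mean log2-ppm abundance exceeds the pooled remaining regions by at
least ``fc_threshold`` (linear scale), and (ii) the BH-adjusted p-value of a
one-way region ANOVA is below ``alpha``.  Because several samples share a
donor, samples are not independent: a single consensus intra-donor
correlation ``rho`` is estimated across proteins and folded into the ANOVA
through a compound-symmetry covariance.  Each donor block is whitened with
the closed-form inverse square root of the compound-symmetry matrix

    y* = (y - c * ybar_block) / sqrt(1 - rho),
    c  = 1 - sqrt((1 - rho) / (1 + (m - 1) * rho)),

for a block of m observed samples, after which an ordinary one-way ANOVA of
region on y* applies with df1 = (regions observed) - 1 and
df2 = n_obs - regions observed.  At rho = 0 the procedure reduces exactly to
the textbook one-way ANOVA.

The consensus correlation is a method-of-moments analogue of limma's
duplicateCorrelation: per protein, residuals about region means are formed,
the within-donor cross-products are pooled, rescaled by an exact
design-based attenuation factor (residuals about fitted region means shrink
the expected cross-product by roughly (1 - 1/n_region)), and divided by the
residual variance.  Per-protein estimates are clamped, Fisher-z transformed,
trimmed-mean averaged and transformed back.  No empirical-Bayes variance
moderation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataio import (
    AbundanceMatrix,
    AnalysisConfig,
    CORTICAL_LOBES,
    Region,
    SampleAnnotation,
    ValidationError,
    annotations_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegionStats",
    "ConsensusCorrelation",
    "SpecificityResult",
    "region_stats",
    "estimate_consensus_correlation",
    "blocked_anova_f",
    "benjamini_hochberg",
    "fold_change_vs_rest",
    "call_region_specific",
    "top_k_per_region",
    "lobe_shared_signature",
]


# ---------------------------------------------------------------------------
# design helpers


@dataclass
class _Design:
    """Aligned array view of a matrix + annotations pair."""

    X: np.ndarray  # proteins x samples, NaN = missing
    protein_ids: list[str]
    sample_ids: list[str]
    regions: list[Region]  # regions present, declaration order
    region_idx: np.ndarray  # sample -> position in `regions`
    donors: list[str]
    donor_idx: np.ndarray  # sample -> position in `donors`

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _make_design(
    matrix: AbundanceMatrix, annotations: Sequence[SampleAnnotation]
) -> _Design:
    ann = annotations_to_frame(annotations)
    missing = [s for s in matrix.sample_ids if s not in ann.index]
    if missing:
        raise ValidationError(f"samples not present in annotations: {missing[:5]}")
    sample_ids = matrix.sample_ids
    region_of = ann.loc[sample_ids, "region"]
    donor_of = ann.loc[sample_ids, "donor_id"]
    regions = [r for r in Region if r.value in set(region_of)]
    region_pos = {r.value: i for i, r in enumerate(regions)}
    donors = sorted(set(donor_of))
    donor_pos = {d: i for i, d in enumerate(donors)}
    return _Design(
        X=matrix.values.to_numpy(dtype=float),
        protein_ids=matrix.protein_ids,
        sample_ids=sample_ids,
        regions=regions,
        region_idx=np.array([region_pos[r] for r in region_of]),
        donors=donors,
        donor_idx=np.array([donor_pos[d] for d in donor_of]),
    )


def _group_stats(X: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """Per-group observation counts, sums and means along samples."""
    obs = ~np.isnan(X)
    filled = np.where(obs, X, 0.0)
    counts = np.zeros((X.shape[0], n_groups))
    sums = np.zeros((X.shape[0], n_groups))
    np.add.at(counts.T, group_idx, obs.T.astype(float))
    np.add.at(sums.T, group_idx, filled.T)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return counts, sums, means


# ---------------------------------------------------------------------------
# region stats


@dataclass
class RegionStats:
    """Per-protein, per-region means and counts of log2-ppm values.

    ``means``/``counts`` are proteins x regions frames (region tokens in
    declaration order); ``linear_means`` carries the arithmetic mean of the
    linear ppm values for the optional linear fold-change scale;
    ``pooled_mean`` is each protein's mean over all observed samples.
    """

    means: pd.DataFrame
    counts: pd.DataFrame
    linear_means: pd.DataFrame
    pooled_mean: pd.Series


def region_stats(
    matrix: AbundanceMatrix, annotations: Sequence[SampleAnnotation]
) -> RegionStats:
    if matrix.stage != "log2ppm":
        raise ValidationError(f"region_stats expects stage log2ppm, got {matrix.stage!r}")
    design = _make_design(matrix, annotations)
    counts, _, means = _group_stats(design.X, design.region_idx, design.n_regions)
    _, lin_sums, lin_means = _group_stats(
        np.exp2(design.X), design.region_idx, design.n_regions
    )
    region_tokens = [r.value for r in design.regions]
    obs = ~np.isnan(design.X)
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pooled = np.where(
            n_obs > 0,
            np.where(obs, design.X, 0.0).sum(axis=1) / np.maximum(n_obs, 1),
            np.nan,
        )
    return RegionStats(
        means=pd.DataFrame(means, index=design.protein_ids, columns=region_tokens),
        counts=pd.DataFrame(
            counts.astype(int), index=design.protein_ids, columns=region_tokens
        ),
        linear_means=pd.DataFrame(
            lin_means, index=design.protein_ids, columns=region_tokens
        ),
        pooled_mean=pd.Series(pooled, index=design.protein_ids, name="pooled_mean"),
    )


# ---------------------------------------------------------------------------
# consensus intra-donor correlation


@dataclass
class ConsensusCorrelation:
    rho_per_protein: pd.Series  # NaN where a protein contributed nothing
    rho_consensus: float
    trim: float
    n_used: int


def _residual_tensors(design: _Design):
    """Residuals about region means plus donor x region incidence tensors."""
    P, S = design.X.shape
    D, R = len(design.donors), design.n_regions
    counts, _, means = _group_stats(design.X, design.region_idx, R)
    resid = design.X - means[:, design.region_idx]
    obs = ~np.isnan(design.X)

    cell = design.donor_idx * R + design.region_idx  # flattened (donor, region)
    N = np.zeros((P, D * R))
    Esum = np.zeros((P, D * R))
    E2sum = np.zeros((P, D * R))
    filled = np.where(obs, resid, 0.0)
    np.add.at(N.T, cell, obs.T.astype(float))
    np.add.at(Esum.T, cell, filled.T)
    np.add.at(E2sum.T, cell, (filled**2).T)
    shape = (P, D, R)
    return counts, resid, obs, N.reshape(shape), Esum.reshape(shape), E2sum.reshape(shape)


def _consensus_pool(design: _Design, config: AnalysisConfig):
    """Per-protein correlation estimates and their trimmed Fisher-z pool.

    Per protein g with residual df >= 3, the estimate is

        rho_g = sum(within-donor cross-products e_a * e_b)
                / (gamma_g * s_g^2)

    where ``s_g^2`` is the residual variance (df = n_obs - regions observed)
    and ``gamma_g`` is the exact expectation coefficient of the pooled
    cross-products under the compound-symmetry model: for a pair of samples
    of one donor in regions r and r' it equals
    ``1 - 1/n_r - 1/n_r' + sum_l c_lr * c_lr'`` with ``c_lr`` donor l's
    share of region r's samples (residuals about fitted region means shrink
    the expected cross-product by roughly 1 - 1/n_region, and gamma undoes
    exactly that).  Only pairs in distinct regions contribute.
    """
    counts, resid, obs, N, Esum, E2sum = _residual_tensors(design)
    n_obs = obs.sum(axis=1)
    n_regions_obs = (counts > 0).sum(axis=1)
    df_resid = n_obs - n_regions_obs
    sse = np.nansum(resid**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df_resid > 0, sse / np.maximum(df_resid, 1), np.nan)

    # cross-region within-donor pair cross-products
    donor_sum = Esum.sum(axis=2)
    donor_sq = E2sum.sum(axis=2)
    pairs_all = (donor_sum**2 - donor_sq) / 2.0
    pairs_same = ((Esum**2 - E2sum) / 2.0).sum(axis=2)
    num = (pairs_all - pairs_same).sum(axis=1)

    # exact expectation coefficient gamma per protein
    n_region = N.sum(axis=1)  # P x R
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(n_region[:, None, :] > 0, N / n_region[:, None, :], 0.0)
    K = np.einsum("pdr,pds->prs", C, C)
    S_N = N.sum(axis=2)
    S_N2 = (N**2).sum(axis=2)
    S_NC = (N * C).sum(axis=2)
    S_N2C = (N**2 * C).sum(axis=2)
    NKN = np.einsum("pdr,prs,pds->pd", N, K, N)
    diagK = np.einsum("prr->pr", K)
    diag_term = (N**2 * diagK[:, None, :]).sum(axis=2)
    gamma = 0.5 * (
        (S_N**2 - S_N2)
        - 2.0 * (S_NC * S_N - S_N2C)
        + (NKN - diag_term)
    ).sum(axis=1)

    valid = (df_resid >= 3) & (gamma > 1e-9) & np.isfinite(s2) & (s2 > 0)
    lo, hi = config.rho_clamp
    rho = np.full(len(design.protein_ids), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho[valid] = np.clip(num[valid] / (gamma[valid] * s2[valid]), lo, hi)
    n_used = int(valid.sum())
    if n_used == 0:
        raise ValidationError(
            "no protein has usable within-donor sample pairs; use blocking='oneway'"
        )
    pooled = float(np.tanh(sps.trim_mean(np.arctanh(rho[valid]), config.trim)))
    return rho, pooled, n_used


def estimate_consensus_correlation(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    config: AnalysisConfig = AnalysisConfig(),
) -> ConsensusCorrelation:
    """Pool a single intra-donor correlation across proteins.

    Per-protein method-of-moments estimates (see ``_consensus_pool``) are
    clamped to ``rho_clamp``, Fisher-z transformed, trimmed-mean averaged
    and transformed back.  Because only a handful of donors inform each
    protein, any correlation-type ratio carries an O(1/n_donors) downward
    finite-sample bias; the reported consensus is therefore the
    delete-one-donor jackknife of the pooled estimate,

        rho = D * rho_all - (D - 1) * mean_j(rho_without_donor_j),

    which removes the first-order bias term.  If a leave-one-out subset is
    too small to estimate (fewer than 2 donors with 2 samples remain), the
    plain pooled estimate is returned.
    """
    if matrix.stage != "log2ppm":
        raise ValidationError("estimate_consensus_correlation expects stage log2ppm")
    design = _make_design(matrix, annotations)
    donor_sizes = np.bincount(design.donor_idx, minlength=len(design.donors))
    if (donor_sizes >= 2).sum() < 2:
        raise ValidationError(
            "need >=2 donors with >=2 samples each to estimate the intra-donor "
            "correlation; use blocking='oneway' instead"
        )
    rho, pooled, n_used = _consensus_pool(design, config)

    consensus = pooled
    ann_list = [
        SampleAnnotation(
            s, design.donors[design.donor_idx[i]], design.regions[design.region_idx[i]]
        )
        for i, s in enumerate(design.sample_ids)
    ]
    try:
        loo = []
        for d_pos in range(len(design.donors)):
            keep_mask = design.donor_idx != d_pos
            keep = [a for a, k in zip(ann_list, keep_mask) if k]
            sub = AbundanceMatrix(
                values=pd.DataFrame(
                    design.X[:, keep_mask],
                    index=design.protein_ids,
                    columns=[a.sample_id for a in keep],
                ),
                stage="log2ppm",
            )
            _, loo_pooled, _ = _consensus_pool(_make_design(sub, keep), config)
            loo.append(loo_pooled)
        D = len(design.donors)
        lo, hi = config.rho_clamp
        consensus = float(np.clip(D * pooled - (D - 1) * np.mean(loo), lo, hi))
    except ValidationError:
        logger.info("jackknife skipped (leave-one-out design too small)")
    logger.info("consensus intra-donor correlation %.4f from %d proteins", consensus, n_used)
    return ConsensusCorrelation(
        rho_per_protein=pd.Series(rho, index=design.protein_ids, name="rho"),
        rho_consensus=consensus,
        trim=config.trim,
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# blocked one-way ANOVA


def _whiten(X: np.ndarray, donor_idx: np.ndarray, n_donors: int, rho: float) -> np.ndarray:
    """Compound-symmetry whitening of each donor block (NaN-aware)."""
    obs = ~np.isnan(X)
    counts, _, bmeans = _group_stats(X, donor_idx, n_donors)
    m = counts[:, donor_idx]  # block size per (protein, sample)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 1.0 - np.sqrt((1.0 - rho) / (1.0 + (m - 1.0) * rho))
    Xw = (X - c * bmeans[:, donor_idx]) / np.sqrt(1.0 - rho)
    return np.where(obs, Xw, np.nan)


def _check_rho(rho: float, max_block: int) -> None:
    if not -1.0 < rho < 1.0 or (max_block > 1 and rho <= -1.0 / (max_block - 1)):
        lower = -1.0 / (max_block - 1) if max_block > 1 else -1.0
        raise ValidationError(
            f"rho={rho} leaves the compound-symmetry covariance non-positive-"
            f"definite for blocks of size {max_block} (need {lower:.4g} < rho < 1)"
        )


def _oneway_f_matrix(Xw: np.ndarray, region_idx: np.ndarray, n_regions: int):
    """Vectorized one-way ANOVA per protein row (NaN-aware)."""
    counts, sums, means = _group_stats(Xw, region_idx, n_regions)
    n_obs = counts.sum(axis=1)
    r_obs = (counts > 0).sum(axis=1)
    grand = np.where(n_obs > 0, sums.sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    with np.errstate(invalid="ignore"):
        ssb = np.nansum(counts * (means - grand[:, None]) ** 2, axis=1)
        fitted = means[:, region_idx]
        ssw = np.nansum((Xw - fitted) ** 2, axis=1)
    df1 = r_obs - 1
    df2 = n_obs - r_obs
    F = np.full(Xw.shape[0], np.nan)
    p = np.full(Xw.shape[0], np.nan)
    ok = (df1 >= 1) & (df2 >= 1)
    tot = ssb + ssw
    degenerate_flat = ok & (tot <= 0)
    F[degenerate_flat], p[degenerate_flat] = 0.0, 1.0
    live = ok & (tot > 0)
    zero_between = live & (ssb <= tot * 1e-12)
    F[zero_between], p[zero_between] = 0.0, 1.0
    zero_within = live & ~zero_between & (ssw <= tot * 1e-12)
    F[zero_within], p[zero_within] = np.inf, 0.0
    rest = live & ~zero_between & ~zero_within
    F[rest] = (ssb[rest] / df1[rest]) / (ssw[rest] / df2[rest])
    p[rest] = sps.f.sf(F[rest], df1[rest], df2[rest])
    return F, df1, df2, p


def blocked_anova_f(
    values: Sequence[float],
    annotations: Sequence[SampleAnnotation],
    rho: float = 0.0,
) -> tuple[float, int, int, float]:
    """Donor-blocked one-way region ANOVA for a single protein.

    ``values`` aligns with ``annotations``; NaN entries are unobserved.
    Returns (F, df1, df2, p).  With rho = 0 this is exactly the textbook
    one-way ANOVA.
    """
    arr = np.asarray(values, dtype=float)[None, :]
    if arr.shape[1] != len(annotations):
        raise ValidationError("values and annotations must align")
    matrix = AbundanceMatrix(
        values=pd.DataFrame(
            arr, index=["_protein"], columns=[a.sample_id for a in annotations]
        ),
        stage="log2ppm",
    )
    design = _make_design(matrix, annotations)
    obs = ~np.isnan(design.X[0])
    if (np.unique(design.region_idx[obs])).size < 2:
        raise ValidationError("need observations in >=2 regions")
    block_sizes = np.bincount(design.donor_idx[obs], minlength=len(design.donors))
    _check_rho(rho, int(block_sizes.max()))
    Xw = _whiten(design.X, design.donor_idx, len(design.donors), rho)
    F, df1, df2, p = _oneway_f_matrix(Xw, design.region_idx, design.n_regions)
    if df2[0] < 1:
        raise ValidationError("residual degrees of freedom < 1")
    return float(F[0]), int(df1[0]), int(df2[0]), float(p[0])


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjustment over the present (non-NaN) p-values.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ) capped at 1, with m the number
    of present values; missing entries stay missing and the input order is
    preserved.  (Equivalent to statsmodels' fdr_bh up to rounding; computed
    directly so the step-up definition holds bit-for-bit.)
    """
    arr = np.asarray(pvals, dtype=float)
    present = ~np.isnan(arr)
    vals = arr[present]
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if vals.size:
        m = vals.size
        order = np.argsort(vals, kind="mergesort")
        scaled = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[present] = restored
    return out


# ---------------------------------------------------------------------------
# fold change and calling


def _max_region_and_fc(stats: RegionStats, fc_scale: str = "log2"):
    """Vectorized max region, tie flag and fold change vs pooled rest."""
    means = stats.means.to_numpy()
    counts = stats.counts.to_numpy().astype(float)
    tokens = list(stats.means.columns)
    observed = counts > 0
    n_regions_obs = observed.sum(axis=1)

    masked = np.where(observed, means, -np.inf)
    max_pos = masked.argmax(axis=1)  # first max = declaration order tie-break
    max_mean = masked[np.arange(len(masked)), max_pos]
    with np.errstate(invalid="ignore"):
        ties = (np.isfinite(max_mean[:, None]) & (masked == max_mean[:, None])).sum(axis=1) > 1

    if fc_scale == "log2":
        level = means
    else:
        level = stats.linear_means.to_numpy()
    sums = np.nansum(np.where(observed, level * counts, 0.0), axis=1)
    n_tot = counts.sum(axis=1)
    level_max = level[np.arange(len(level)), max_pos]
    n_max = counts[np.arange(len(counts)), max_pos]
    with np.errstate(invalid="ignore", divide="ignore"):
        rest_mean = (sums - level_max * n_max) / (n_tot - n_max)
        if fc_scale == "log2":
            fc = np.exp2(level_max - rest_mean)
        else:
            fc = level_max / rest_mean
    fc = np.where(n_regions_obs >= 2, fc, np.nan)
    max_region = np.where(
        n_regions_obs >= 1, np.array(tokens, dtype=object)[max_pos], None
    )
    return max_region, ties & (n_regions_obs >= 1), fc, max_pos, n_max, n_regions_obs


def fold_change_vs_rest(
    stats: RegionStats, protein_id: str, fc_scale: str = "log2"
) -> tuple[Region, bool, float]:
    """Max-mean region, tie flag and fold change vs the pooled remaining
    regions for one protein.

    The fold change compares the max region's mean with the mean over all
    observed samples pooled from the remaining regions; on the default log2
    scale it is the geometric-mean ratio ``2**(mean_max - mean_rest)``.
    Ties are broken by region declaration order and flagged.
    """
    sub = RegionStats(
        means=stats.means.loc[[protein_id]],
        counts=stats.counts.loc[[protein_id]],
        linear_means=stats.linear_means.loc[[protein_id]],
        pooled_mean=stats.pooled_mean.loc[[protein_id]],
    )
    max_region, tie, fc, _, _, n_regions_obs = _max_region_and_fc(sub, fc_scale)
    if n_regions_obs[0] < 2:
        raise ValidationError(f"protein {protein_id!r} observed in <2 regions")
    return Region(max_region[0]), bool(tie[0]), float(fc[0])


@dataclass
class SpecificityResult:
    """Output of the calling pipeline.

    ``table`` has one row per protein (max region, tie flag, fold change,
    blocked F with degrees of freedom, raw and BH-adjusted p, testability
    and call flags, plus the per-region mean log2-ppm columns).  ``rho``
    is the correlation used for whitening and ``consensus`` the estimator
    output (None under blocking='oneway').
    """

    table: pd.DataFrame
    rho: float
    consensus: ConsensusCorrelation | None
    config: AnalysisConfig

    @property
    def calls(self) -> pd.DataFrame:
        return self.table[self.table["call"]]


def call_region_specific(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    config: AnalysisConfig = AnalysisConfig(),
) -> SpecificityResult:
    """The full calling pipeline on a log2-ppm matrix.

    Stages: region stats -> consensus correlation (if blocking='blocked')
    -> per-protein blocked F -> BH over testable proteins -> fold change.
    A protein is testable iff >= ``min_testable_regions`` regions have an
    observation and the residual df is >= 1; a call additionally requires
    p_adj < alpha, fc >= fc_threshold and >= ``min_obs_max_region``
    observations in the top region.
    """
    if matrix.stage != "log2ppm":
        raise ValidationError("call_region_specific expects stage log2ppm")
    design = _make_design(matrix, annotations)
    stats = region_stats(matrix, annotations)

    consensus: ConsensusCorrelation | None = None
    rho = 0.0
    if config.blocking == "blocked":
        consensus = estimate_consensus_correlation(matrix, annotations, config)
        rho = consensus.rho_consensus

    obs = ~np.isnan(design.X)
    block_sizes = np.zeros((design.X.shape[0], len(design.donors)))
    np.add.at(block_sizes.T, design.donor_idx, obs.T.astype(float))
    _check_rho(rho, int(block_sizes.max()) if block_sizes.size else 1)

    Xw = _whiten(design.X, design.donor_idx, len(design.donors), rho)
    F, df1, df2, p = _oneway_f_matrix(Xw, design.region_idx, design.n_regions)

    counts = stats.counts.to_numpy()
    n_regions_obs = (counts > 0).sum(axis=1)
    testable = (n_regions_obs >= config.min_testable_regions) & (df2 >= 1)
    p_masked = np.where(testable, p, np.nan)
    p_adj = benjamini_hochberg(p_masked)

    max_region, tie_flag, fc, max_pos, n_max, _ = _max_region_and_fc(
        stats, config.fc_scale
    )
    with np.errstate(invalid="ignore"):
        call = (
            testable
            & (p_adj < config.alpha)
            & (fc >= config.fc_threshold)
            & (n_max >= config.min_obs_max_region)
        )
    call = np.where(np.isnan(fc), False, call).astype(bool)

    table = pd.DataFrame(
        {
            "protein_id": design.protein_ids,
            "max_region": pd.array(max_region, dtype="string"),
            "tie_flag": tie_flag,
            "fc_vs_rest": fc,
            "F": np.where(testable, F, np.nan),
            "df1": np.where(testable, df1, np.nan),
            "df2": np.where(testable, df2, np.nan),
            "p": np.where(testable, p, np.nan),
            "p_adj": p_adj,
            "testable": testable,
            "call": call,
        }
    )
    mean_cols = stats.means.add_prefix("mean_").reset_index(drop=True)
    table = pd.concat([table, mean_cols], axis=1)
    logger.info(
        "called %d of %d proteins region-specific (rho=%.4f)",
        int(call.sum()),
        len(table),
        rho,
    )
    return SpecificityResult(table=table, rho=rho, consensus=consensus, config=config)


def top_k_per_region(table: pd.DataFrame, k: int = 13) -> pd.DataFrame:
    """Top-k called proteins per region, ranked by fold change.

    Ties in fold change are broken by protein_id so the ranking is
    reproducible.  Returns a long table (region, rank, protein_id,
    fc_vs_rest) with at most k rows per region.
    """
    calls = table[table["call"]].copy()
    out_rows = []
    for region in Region:
        block = calls[calls["max_region"] == region.value]
        block = block.sort_values(
            ["fc_vs_rest", "protein_id"], ascending=[False, True]
        ).head(k)
        for rank, row in enumerate(block.itertuples(), start=1):
            out_rows.append(
                {
                    "region": region.value,
                    "rank": rank,
                    "protein_id": row.protein_id,
                    "fc_vs_rest": row.fc_vs_rest,
                }
            )
    return pd.DataFrame(out_rows, columns=["region", "rank", "protein_id", "fc_vs_rest"])


def lobe_shared_signature(
    matrix: AbundanceMatrix,
    annotations: Sequence[SampleAnnotation],
    config: AnalysisConfig = AnalysisConfig(),
    spec_result: SpecificityResult | None = None,
) -> pd.DataFrame:
    """Proteins commonly elevated in all four cortical lobes.

    A protein belongs to the shared cortical signature when, for each of
    FL, TL, PL and OL, its lobe mean exceeds the pooled noncortical mean by
    at least ``fc_threshold`` (same scale convention as the main fold
    change), and its overall region-ANOVA p_adj is below ``alpha``.
    Returns the included proteins with their per-lobe fold changes.
    """
    if matrix.stage != "log2ppm":
        raise ValidationError("lobe_shared_signature expects stage log2ppm")
    stats = region_stats(matrix, annotations)
    tokens = list(stats.means.columns)
    lobe_tokens = [r.value for r in CORTICAL_LOBES]
    missing_lobes = [t for t in lobe_tokens if t not in tokens]
    if missing_lobes:
        raise ValidationError(f"design lacks cortical lobes: {missing_lobes}")
    noncort = [t for t in tokens if t not in lobe_tokens]
    if not noncort:
        raise ValidationError("design has no noncortical region")

    if spec_result is None:
        spec_result = call_region_specific(matrix, annotations, config)
    p_adj = spec_result.table.set_index("protein_id")["p_adj"]

    means = stats.means
    counts = stats.counts
    if config.fc_scale == "log2":
        level = means
    else:
        level = stats.linear_means
    nc_counts = counts[noncort].to_numpy().astype(float)
    nc_sums = np.nansum(
        np.where(nc_counts > 0, level[noncort].to_numpy() * nc_counts, 0.0), axis=1
    )
    nc_n = nc_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc_mean = np.where(nc_n > 0, nc_sums / np.maximum(nc_n, 1), np.nan)

    fcs = {}
    for lobe in lobe_tokens:
        lobe_level = level[lobe].to_numpy()
        if config.fc_scale == "log2":
            fcs[f"fc_{lobe}"] = np.exp2(lobe_level - nc_mean)
        else:
            fcs[f"fc_{lobe}"] = lobe_level / nc_mean
    fc_frame = pd.DataFrame(fcs, index=means.index)
    with np.errstate(invalid="ignore"):
        passes = (fc_frame >= config.fc_threshold).all(axis=1) & fc_frame.notna().all(
            axis=1
        )
    sig = passes & (p_adj.reindex(means.index) < config.alpha)
    out = fc_frame[sig].copy()
    out.insert(0, "protein_id", out.index)
    out["p_adj"] = p_adj.reindex(out.index)
    return out.reset_index(drop=True)
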