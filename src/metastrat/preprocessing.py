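"""Dataset pretreatment: KNN missing-value imputation, then MSTUS.

The order is fixed — impute first, then normalize — and MSTUS uses the
set of features that were observed in every sample *before* imputation
as its "total useful signal" denominator.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_formats import PeakTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PretreatConfig:
    k: int = 10
    min_neighbor_overlap: int = 3

    def validate(self, n_features: int) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k >= n_features:
            raise ValueError(
                f"k={self.k} must be smaller than the number of features "
                f"({n_features})"
            )


def _neighbor_distances(x: np.ndarray, f: int, observed: np.ndarray,
                        min_overlap: int) -> np.ndarray:
    """Feature-to-feature distances from row f, NaN where ineligible.

    Euclidean distance over mutually observed samples, rescaled by
    sqrt(n_samples / n_overlap) so features with few shared samples are
    not spuriously close (the nan-Euclidean convention).  Neighbors with
    fewer than ``min_overlap`` mutually observed samples are ineligible;
    if the target feature itself has fewer observed values than
    ``min_overlap`` the requirement relaxes to what is attainable.
    """
    n_feat, n_samp = x.shape
    obs_f = observed[f]
    required = min(min_overlap, int(obs_f.sum()))
    mutual = observed & obs_f[None, :]
    n_mutual = mutual.sum(axis=1)
    diff = np.where(mutual, x - x[f], 0.0)
    ssq = np.einsum("ij,ij->i", diff, diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(ssq * n_samp / n_mutual)
    dist[n_mutual < required] = np.nan
    dist[f] = np.nan
    return dist


def knn_impute(table: PeakTable, k: int = 10,
               min_neighbor_overlap: int = 3) -> PeakTable:
    """Fill missing cells from the k most similar features.

    Each missing cell (feature f, sample s) becomes the mean over the k
    nearest eligible features — nearest by Euclidean distance computed on
    mutually observed samples — of their values in sample s.  Only
    neighbors actually observed in s are eligible for that cell; when no
    eligible neighbor exists, the feature's own observed mean is used and
    a warning is logged.  Observed cells are never modified.
    """
    cfg = PretreatConfig(k=k, min_neighbor_overlap=min_neighbor_overlap)
    cfg.validate(table.n_features)
    x = table.intensities
    observed = ~np.isnan(x)
    n_obs_per_feature = observed.sum(axis=1)
    if np.any(n_obs_per_feature == 0):
        bad = int(np.argmax(n_obs_per_feature == 0))
        raise ValueError(
            f"feature row {bad} (m/z {table.mz[bad]:.4f}) has no observed "
            "values; remove it before imputation"
        )
    if observed.all():
        return table.copy()

    out = x.copy()
    feature_means = np.nansum(x, axis=1) / n_obs_per_feature
    n_fallback = 0
    for f in np.flatnonzero(~observed.all(axis=1)):
        dist = _neighbor_distances(x, f, observed, min_neighbor_overlap)
        for s in np.flatnonzero(~observed[f]):
            cand = np.isfinite(dist) & observed[:, s]
            if not cand.any():
                out[f, s] = feature_means[f]
                n_fallback += 1
                continue
            cand_idx = np.flatnonzero(cand)
            order = cand_idx[np.argsort(dist[cand_idx], kind="stable")]
            out[f, s] = float(np.mean(x[order[:k], s]))
    if n_fallback:
        logger.warning(
            "KNN imputation fell back to feature means for %d cells "
            "(no eligible neighbor observed in the sample)", n_fallback
        )
    result = table.copy()
    result.intensities = out
    return result


def shared_feature_mask(table: PeakTable) -> np.ndarray:
    """Features observed in every sample (the MSTUS denominator set)."""
    return ~np.isnan(table.intensities).any(axis=1)


def mstus_normalize(table: PeakTable,
                    shared: np.ndarray | None = None) -> PeakTable:
    """Divide each sample by its total signal over the shared feature set.

    ``shared`` should be the pre-imputation fully-observed feature mask;
    when omitted it is derived from the current table (features with no
    missing entries).  If no feature is shared by all samples, falls back
    to total-signal normalization over all features with a warning.
    """
    x = table.intensities
    if np.isnan(x).any():
        raise ValueError("mstus_normalize requires a fully imputed table")
    if shared is None:
        shared = shared_feature_mask(table)
    shared = np.asarray(shared, dtype=bool)
    if shared.shape != (table.n_features,):
        raise ValueError("shared mask length does not match feature count")
    if not shared.any():
        logger.warning(
            "no feature shared by all samples; falling back to "
            "total-signal normalization over all features"
        )
        shared = np.ones(table.n_features, dtype=bool)
    totals = x[shared].sum(axis=0)
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has non-positive shared-feature total")
    result = table.copy()
    result.intensities = x / totals[None, :]
    return result


def pretreat(table: PeakTable, k: int = 10,
             min_neighbor_overlap: int = 3) -> PeakTable:
    """Impute with KNN, then MSTUS-normalize using the pre-imputation
    fully-observed feature set as the shared signal."""
    shared = shared_feature_mask(table)
    imputed = knn_impute(table, k=k, min_neighbor_overlap=min_neighbor_overlap)
    return mstus_normalize(imputed, shared=shared)
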