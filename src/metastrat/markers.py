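"""Differential-feature identification and metabolite annotation.

Markers are called either by a per-feature two-sample Student's t-test
(pooled variance, two-sided, no multiplicity correction) or by the
conjunction of a PLS-DA VIP threshold with that same t-test.  Peaks are
annotated against a reference library within a ppm window around the
protonated/deprotonated expected m/z.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .io_formats import PeakTable, ReferenceLibrary

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276


@dataclasses.dataclass
class MarkerItem:
    feature_key: tuple[float, float]
    p_value: float
    vip: float | None = None


@dataclasses.dataclass
class MarkerList:
    """Selected features with their per-item statistics."""

    items: list[MarkerItem]

    def __post_init__(self) -> None:
        keys = [it.feature_key for it in self.items]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate feature key in marker list")
        for it in self.items:
            if not 0 <= it.p_value <= 1:
                raise ValueError(f"p-value out of [0,1]: {it.p_value}")

    @property
    def feature_keys(self) -> list[tuple[float, float]]:
        return [it.feature_key for it in self.items]

    def key_set(self) -> frozenset[tuple[float, float]]:
        return frozenset(it.feature_key for it in self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclasses.dataclass
class AnnotationResult:
    """One-to-many peak-to-metabolite mapping at a ppm tolerance."""

    mapping: dict[tuple[float, float], list[str]]
    universe: frozenset[str]

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def metabolites_for(
        self, keys: list[tuple[float, float]]
    ) -> frozenset[str]:
        out: set[str] = set()
        for k in keys:
            out.update(self.mapping.get(k, ()))
        return frozenset(out)


def feature_pvalues(table: PeakTable, equal_var: bool = True) -> np.ndarray:
    """Two-sided two-sample t-test p-value per feature.

    Pooled-variance (Student's) by default.  Features with zero variance
    in both groups get p = 1 by convention (logged).  Missing entries are
    ignored per feature.
    """
    case = table.intensities[:, table.case_mask]
    control = table.intensities[:, table.control_mask]
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need >= 2 samples per group for the t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=equal_var,
                              nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d features with degenerate t statistics (zero pooled "
            "variance); p set to 1", int(degenerate.sum())
        )
        p[degenerate] = 1.0
    return p


def ttest_markers(table: PeakTable, alpha: float = 0.05,
                  equal_var: bool = True) -> MarkerList:
    """Features with Student's-t p < alpha (no multiplicity correction)."""
    p = feature_pvalues(table, equal_var=equal_var)
    keys = table.feature_keys
    return MarkerList([
        MarkerItem(feature_key=keys[i], p_value=float(p[i]))
        for i in np.flatnonzero(p < alpha)
    ])


def plsda_vip(table: PeakTable, n_components: int = 2) -> np.ndarray:
    """Per-feature VIP scores from a PLS-DA model of the group contrast.

    Features are autoscaled (mean-centred, unit variance; constant
    features get a unit-variance guard) and the binary group indicator is
    regressed by PLS.  VIP_j = sqrt(P * sum_a SSY_a w_ja^2 / sum_a SSY_a)
    with normalized weight vectors, so sum_j VIP_j^2 = P exactly.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.isnan(table.intensities).any():
        raise ValueError("plsda_vip requires a fully imputed table")
    x = table.intensities.T.astype(float)          # samples x features
    y = table.case_mask.astype(float)
    n, p = x.shape
    n_components = min(n_components, max(1, min(n - 1, p)))

    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant features; unit-variance guard applied",
                       int(constant.sum()))
        sd = np.where(constant, 1.0, sd)
    xs = (x - mu) / sd
    ys = y - y.mean()

    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(xs, ys)
    w = model.x_weights_                            # (p, A)
    t = model.x_scores_                             # (n, A)
    q = model.y_loadings_.ravel()                   # (A,)
    ssy = np.sum(t ** 2, axis=0) * q ** 2           # y-variance per component
    w_norm = w / np.linalg.norm(w, axis=0, keepdims=True)
    vip = np.sqrt(p * (w_norm ** 2 @ ssy) / ssy.sum())
    return vip


def plsda_markers(table: PeakTable, vip_threshold: float = 1.0,
                  alpha: float = 0.05, n_components: int = 2) -> MarkerList:
    """Features with VIP > threshold AND Student's-t p < alpha."""
    vip = plsda_vip(table, n_components=n_components)
    p = feature_pvalues(table)
    keys = table.feature_keys
    sel = (vip > vip_threshold) & (p < alpha)
    return MarkerList([
        MarkerItem(feature_key=keys[i], p_value=float(p[i]),
                   vip=float(vip[i]))
        for i in np.flatnonzero(sel)
    ])


def annotate(feature_keys: list[tuple[float, float]],
             lib: ReferenceLibrary, tol_ppm: float = 20.0,
             mode: str = "positive") -> AnnotationResult:
    """Map each peak to all library records within the ppm window.

    A feature at observed m/z matches a record iff
    ``|observed - expected| <= tol_ppm * 1e-6 * expected`` where the
    expected m/z is the neutral mass plus (positive mode) or minus
    (negative mode) one proton.
    """
    if len(lib) == 0:
        raise ValueError("empty reference library")
    if mode not in ("positive", "negative"):
        raise ValueError("mode must be 'positive' or 'negative'")
    sign = 1.0 if mode == "positive" else -1.0
    expected = lib.neutral_masses + sign * PROTON_MASS
    order = np.argsort(expected, kind="stable")
    exp_sorted = expected[order]
    half = tol_ppm * 1e-6 * exp_sorted

    mapping: dict[tuple[float, float], list[str]] = {}
    universe: set[str] = set()
    for key in feature_keys:
        obs = key[0]
        # window: expected in [obs/(1+tol), obs/(1-tol)] approx; bracket
        # generously then filter exactly
        tol = tol_ppm * 1e-6
        lo = np.searchsorted(exp_sorted, obs * (1 - 2 * tol), side="left")
        hi = np.searchsorted(exp_sorted, obs * (1 + 2 * tol), side="right")
        hits = [
            lib.metabolite_ids[int(order[pos])]
            for pos in range(lo, hi)
            if abs(obs - exp_sorted[pos]) <= half[pos]
        ]
        mapping[key] = hits
        universe.update(hits)
    return AnnotationResult(mapping=mapping, universe=frozenset(universe))
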