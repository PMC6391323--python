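"""Synthetic dual-experiment generator with planted ground truth.

Produces a pair of peak tables that mimic two LC-MS experiments measuring
overlapping feature sets on the same case/control contrast: log-normal
intensities, differential features shifted consistently in both
experiments, experiment-level location/scale perturbations, m/z
measurement jitter between experiments, and intensity-dependent
missingness.  A matching reference library (true records plus near-mass
decoys) and a ground-truth object make every downstream stage testable
without external data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_formats import (
    GROUP_CASE,
    GROUP_CONTROL,
    PeakTable,
    ReferenceLibrary,
    TrueMarkerSet,
)

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs for :func:`generate_pair`.

    ``effect_size`` is the case-vs-control mean shift in units of the
    per-feature log-scale SD.  ``batch_location_shift`` is an additive
    log-scale offset applied to every sample of experiment 2 and
    ``batch_scale`` multiplies experiment 2's log-scale noise SD, so the
    two batch knobs perturb location and dispersion independently.
    ``mnar_weight`` is the fraction of missing cells concentrated in the
    lowest-intensity stratum (the rest are missing completely at random).
    """

    n_features_shared: int = 300
    n_features_unique: int = 50
    n_case: int = 30
    n_control: int = 30
    n_true_markers: int = 20
    effect_size: float = 1.0
    batch_location_shift: float = 0.5
    batch_scale: float = 1.2
    missing_rate: float = 0.0
    mnar_weight: float = 0.5
    mz_jitter: float = 0.0
    decoy_rate: float = 2.0
    mode: str = "positive"
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_features_shared", "n_features_unique", "n_case",
                     "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_true_markers < 0:
            raise ValueError("n_true_markers must be >= 0")
        if self.n_true_markers > self.n_features_shared:
            raise ValueError(
                "n_true_markers exceeds n_features_shared: "
                f"{self.n_true_markers} > {self.n_features_shared}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.mnar_weight <= 1:
            raise ValueError("mnar_weight must be in [0, 1]")
        if self.mz_jitter < 0 or self.decoy_rate < 0:
            raise ValueError("mz_jitter and decoy_rate must be >= 0")
        if self.batch_scale <= 0:
            raise ValueError("batch_scale must be > 0")
        if self.mode not in ("positive", "negative"):
            raise ValueError("mode must be 'positive' or 'negative'")


@dataclasses.dataclass
class GroundTruth:
    """Planted truth accompanying a generated experiment pair."""

    true_feature_keys_a: list[tuple[float, float]]
    true_feature_keys_b: list[tuple[float, float]]
    true_metabolite_ids: frozenset[str]
    feature_to_metabolite_a: dict[tuple[float, float], str]
    feature_to_metabolite_b: dict[tuple[float, float], str]
    shared_keys_a: list[tuple[float, float]]
    shared_keys_b: list[tuple[float, float]]

    def true_marker_set(self) -> TrueMarkerSet:
        return TrueMarkerSet(self.true_metabolite_ids)


def _spaced_mz(rng: np.random.Generator, n: int, lo: float = 100.0,
               hi: float = 1000.0, min_gap: float = 0.1) -> np.ndarray:
    """Draw n sorted m/z values with pairwise spacing >= min_gap."""
    span = hi - lo - n * min_gap
    if span <= 0:
        raise ValueError("m/z range too narrow for requested feature count")
    u = np.sort(rng.uniform(0.0, span, size=n))
    return lo + u + min_gap * np.arange(n)


def _apply_missingness(rng: np.random.Generator, x: np.ndarray,
                       missing_rate: float, mnar_weight: float) -> np.ndarray:
    """Censor cells: MNAR in the low-intensity stratum, remainder MCAR.

    Guarantees every feature keeps at least two observed values per group
    boundary-free (at least 2 observed overall) so imputation stays
    well-posed.
    """
    if missing_rate == 0:
        return x
    out = x.copy()
    flat = out.ravel()
    n_cells = flat.size
    n_missing = int(round(missing_rate * n_cells))
    n_mnar = int(round(mnar_weight * n_missing))
    order = np.argsort(flat)
    # lowest-intensity stratum: twice the MNAR budget, sampled without
    # replacement so censoring is stochastic rather than a hard threshold
    stratum = order[: min(2 * n_mnar, n_cells)] if n_mnar else np.array([], int)
    mnar_idx = (rng.choice(stratum, size=n_mnar, replace=False)
                if n_mnar else np.array([], int))
    remaining = np.setdiff1d(np.arange(n_cells), mnar_idx, assume_unique=False)
    n_mcar = n_missing - n_mnar
    mcar_idx = (rng.choice(remaining, size=n_mcar, replace=False)
                if n_mcar > 0 else np.array([], int))
    kill = np.concatenate([mnar_idx, mcar_idx])
    flat[kill] = np.nan
    out = flat.reshape(x.shape)
    # keep >= 2 observed entries per feature
    for f in range(out.shape[0]):
        obs = ~np.isnan(out[f])
        if obs.sum() < 2:
            need = 2 - int(obs.sum())
            candidates = np.flatnonzero(~obs)
            restore = rng.choice(candidates, size=need, replace=False)
            out[f, restore] = x[f, restore]
    return out


def generate_pair(
    config: SyntheticConfig,
) -> tuple[PeakTable, PeakTable, ReferenceLibrary, GroundTruth]:
    """Generate two experiments, their library and the planted ground truth.

    All randomness flows from ``config.seed``; identical configs give
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_shared = config.n_features_shared
    n_unique = config.n_features_unique
    n_total = n_shared + 2 * n_unique

    mz_all = _spaced_mz(rng, n_total)
    perm = rng.permutation(n_total)
    shared_idx = perm[:n_shared]
    unique_a_idx = perm[n_shared:n_shared + n_unique]
    unique_b_idx = perm[n_shared + n_unique:]

    rt_all = rng.uniform(10.0, 600.0, size=n_total)
    base_mu = rng.normal(10.0, 1.0, size=n_total)      # log-intensity means
    sigma = rng.uniform(0.3, 0.7, size=n_total)         # log-scale SDs

    marker_local = rng.choice(n_shared, size=config.n_true_markers,
                              replace=False)
    marker_global = shared_idx[marker_local]
    is_marker = np.zeros(n_total, dtype=bool)
    is_marker[marker_global] = True

    def build_experiment(tag: str, feat_idx: np.ndarray,
                         loc_shift: float, scale: float,
                         jitter: np.ndarray) -> PeakTable:
        n_feat = feat_idx.size
        n_samp = config.n_case + config.n_control
        groups = np.array([GROUP_CASE] * config.n_case +
                          [GROUP_CONTROL] * config.n_control, dtype=object)
        mu = base_mu[feat_idx][:, None] + loc_shift
        sd = sigma[feat_idx][:, None] * scale
        shift = (config.effect_size * sigma[feat_idx])[:, None] * \
            is_marker[feat_idx][:, None]
        log_x = mu + shift * (groups == GROUP_CASE)[None, :] + \
            rng.normal(0.0, 1.0, size=(n_feat, n_samp)) * sd
        x = np.exp(log_x)
        x = _apply_missingness(rng, x, config.missing_rate,
                               config.mnar_weight)
        return PeakTable(
            mz=mz_all[feat_idx] + jitter,
            rt=rt_all[feat_idx],
            intensities=x,
            sample_ids=[f"{tag}_S{i:03d}" for i in range(n_samp)],
            groups=groups,
            experiments=np.array([tag] * n_samp, dtype=object),
        )

    feat_a = np.concatenate([shared_idx, unique_a_idx])
    feat_b = np.concatenate([shared_idx, unique_b_idx])
    jitter_a = np.zeros(feat_a.size)
    jitter_b = np.zeros(feat_b.size)
    if config.mz_jitter > 0:
        jitter_b[:n_shared] = rng.uniform(-config.mz_jitter, config.mz_jitter,
                                          size=n_shared)
    table_a = build_experiment("EXP1", feat_a, 0.0, 1.0, jitter_a)
    table_b = build_experiment("EXP2", feat_b, config.batch_location_shift,
                               config.batch_scale, jitter_b)

    # library: one true record per generated feature + Poisson decoys
    # within the 20 ppm annotation window, so annotation is one-to-many
    sign = 1.0 if config.mode == "positive" else -1.0
    lib_ids: list[str] = []
    lib_names: list[str] = []
    lib_masses: list[float] = []
    feature_metabolite = {}
    for gi in range(n_total):
        mid = f"M{gi:06d}"
        feature_metabolite[gi] = mid
        lib_ids.append(mid)
        lib_names.append(f"metabolite_{gi:06d}")
        lib_masses.append(mz_all[gi] - sign * PROTON_MASS)
        for d in range(rng.poisson(config.decoy_rate)):
            rel = rng.uniform(-15e-6, 15e-6)
            lib_ids.append(f"D{gi:06d}_{d}")
            lib_names.append(f"decoy_{gi:06d}_{d}")
            lib_masses.append((mz_all[gi] - sign * PROTON_MASS) * (1 + rel))
    library = ReferenceLibrary(lib_ids, lib_names, np.asarray(lib_masses))

    shared_keys_a = [table_a.feature_keys[i] for i in range(n_shared)]
    shared_keys_b = [table_b.feature_keys[i] for i in range(n_shared)]
    marker_pos = {int(g): i for i, g in enumerate(feat_a[:n_shared])
                  if is_marker[g]}
    true_keys_a = [table_a.feature_keys[i]
                   for g, i in sorted(marker_pos.items())]
    true_keys_b = [table_b.feature_keys[i]
                   for g, i in sorted(marker_pos.items())]

    f2m_a = {table_a.feature_keys[i]: feature_metabolite[int(g)]
             for i, g in enumerate(feat_a)}
    f2m_b = {table_b.feature_keys[i]: feature_metabolite[int(g)]
             for i, g in enumerate(feat_b)}
    truth = GroundTruth(
        true_feature_keys_a=true_keys_a,
        true_feature_keys_b=true_keys_b,
        true_metabolite_ids=frozenset(feature_metabolite[int(g)]
                                      for g in marker_global),
        feature_to_metabolite_a=f2m_a,
        feature_to_metabolite_b=f2m_b,
        shared_keys_a=shared_keys_a,
        shared_keys_b=shared_keys_b,
    )
    return table_a, table_b, library, truth


def plant_summary(config: SyntheticConfig, gt: GroundTruth) -> dict[str, int]:
    """Counts of shared/unique/true features for report headers."""
    return {
        "n_shared": len(gt.shared_keys_a),
        "n_unique_per_experiment": config.n_features_unique,
        "n_true_markers": len(gt.true_feature_keys_a),
        "n_true_metabolites": len(gt.true_metabolite_ids),
    }
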