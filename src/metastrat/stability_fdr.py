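"""Marker robustness (half-sampling overlap) and enrichment-factor scoring.

Robustness: draw ten stratified half-samples of the pretreated table,
call t-test markers in each, and summarize all C(10,2)=45 pairwise Dice
overlaps plus the co-identification profile (markers found in N of the
ten lists).  False-discovery control: enrichment factor — the true-marker
rate among identified metabolites relative to the rate in the detected
annotated universe (EF = 1 is random selection).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import PeakTable, TrueMarkerSet
from .markers import AnnotationResult, MarkerList, ttest_markers

logger = logging.getLogger(__name__)

COIDENT_LEVELS = ("10", ">=9", ">=8", ">=7", ">=6")


def half_sample(table: PeakTable, seed: int) -> PeakTable:
    """Stratified draw of floor(n_g/2) samples per group, no replacement."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for group in sorted(set(table.groups)):
        idx = np.flatnonzero(table.groups == group)
        if idx.size < 4:
            raise ValueError(
                f"group {group!r} has {idx.size} samples; need >= 4 "
                "for half-sampling"
            )
        keep.extend(rng.choice(idx, size=idx.size // 2,
                               replace=False).tolist())
    return table.subset_samples(np.sort(np.array(keep, dtype=int)))


def overlap(a: MarkerList | Iterable, b: MarkerList | Iterable) -> float:
    """Dice-type overlap 2|a∩b| / (|a|+|b|); two empty lists give 0."""
    sa = a.key_set() if isinstance(a, MarkerList) else frozenset(a)
    sb = b.key_set() if isinstance(b, MarkerList) else frozenset(b)
    if not sa and not sb:
        logger.warning("overlap of two empty marker lists; returning 0")
        return 0.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def coidentification_percentage(count: int, total_identified: int) -> float:
    """Percentage convention of the co-identification profile, 2 d.p."""
    if total_identified == 0:
        return 0.0
    return round(100.0 * count / total_identified, 2)


@dataclasses.dataclass
class OverlapReport:
    """Result of the half-sampling robustness protocol."""

    n_iterations: int
    marker_counts: list[float]
    overlaps: list[float]
    median_overlap: float
    total_identified: float
    coidentification: dict[str, tuple[float, float]]  # level -> (count, %)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coidentification"] = {
            k: {"count": v[0], "percent": v[1]}
            for k, v in self.coidentification.items()
        }
        return d


def _pair_order(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def coidentification_profile(
    marker_sets: Sequence[frozenset],
) -> tuple[float, dict[str, tuple[float, float]]]:
    """Union size and the (count, percent) profile at N = 10, >=9 ... >=6."""
    n = len(marker_sets)
    counts = Counter()
    for s in marker_sets:
        counts.update(s)
    union_size = len(counts)
    freq = np.array(list(counts.values())) if counts else np.array([], int)
    profile: dict[str, tuple[float, float]] = {}
    for level in COIDENT_LEVELS:
        thr = n if level == "10" else int(level[2:])
        c = int((freq >= thr).sum()) if level != "10" else \
            int((freq == n).sum())
        profile[level] = (c, coidentification_percentage(c, union_size))
    return union_size, profile


def robustness_report(table: PeakTable, n_iter: int = 10,
                      alpha: float = 0.05, seed: int = 0) -> OverlapReport:
    """Run the half-sampling protocol and collect all pairwise overlaps.

    ``n_iter`` half-samples each yield a t-test marker list; the report
    holds the C(n_iter, 2) overlaps in (i, j), i < j order, their median,
    the union size across lists, and the co-identification profile with
    percentages over that union.
    """
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_iter)]
    marker_sets: list[frozenset] = []
    marker_counts: list[float] = []
    for it in range(n_iter):
        sub = half_sample(table, seed=child_seeds[it])
        mk = ttest_markers(sub, alpha=alpha)
        marker_sets.append(mk.key_set())
        marker_counts.append(float(len(mk)))
    overlaps = [overlap(marker_sets[i], marker_sets[j])
                for i, j in _pair_order(n_iter)]
    union_size, profile = coidentification_profile(marker_sets)
    return OverlapReport(
        n_iterations=n_iter,
        marker_counts=marker_counts,
        overlaps=overlaps,
        median_overlap=float(np.median(overlaps)) if overlaps else 0.0,
        total_identified=float(union_size),
        coidentification=profile,
    )


def integrate_robustness(a: OverlapReport, b: OverlapReport) -> OverlapReport:
    """Results-integration robustness: average the two experiments pairwise.

    Overlap (i, j) of the integrated report is the mean of the two
    experiments' (i, j) overlaps; per-iteration marker counts, union size
    and co-identification counts are likewise two-experiment means.
    """
    if a.n_iterations != b.n_iterations:
        raise ValueError("reports have different iteration counts")
    overlaps = [0.5 * (x + y) for x, y in zip(a.overlaps, b.overlaps)]
    total = 0.5 * (a.total_identified + b.total_identified)
    coident: dict[str, tuple[float, float]] = {}
    for level in COIDENT_LEVELS:
        c = 0.5 * (a.coidentification[level][0] + b.coidentification[level][0])
        pct = round(100.0 * c / total, 2) if total else 0.0
        coident[level] = (c, pct)
    return OverlapReport(
        n_iterations=a.n_iterations,
        marker_counts=[0.5 * (x + y)
                       for x, y in zip(a.marker_counts, b.marker_counts)],
        overlaps=overlaps,
        median_overlap=float(np.median(overlaps)) if overlaps else 0.0,
        total_identified=total,
        coidentification=coident,
    )


def compare_overlap_distributions(x: Sequence[float],
                                  y: Sequence[float]) -> tuple[float, bool]:
    """One-sided Wilcoxon rank-sum p for "x stochastically greater than y".

    Returns (p_value, degenerate_flag); all-tied inputs give p = 1 with
    the flag set.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both overlap lists must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        logger.warning("all overlap values tied; comparison degenerate")
        return 1.0, True
    res = stats.mannwhitneyu(x, y, alternative="greater")
    return float(res.pvalue), False


# ---------------------------------------------------------------------------
# enrichment factor
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EFReport:
    """Enrichment-factor bookkeeping mirroring the benchmark table layout."""

    n_detected_annotated: int
    n_true_detected: int
    n_identified_annotated: int
    n_true_identified: int
    ef: float
    flags: tuple[str, ...] = ()
    universe_ids: frozenset = dataclasses.field(default_factory=frozenset)
    identified_ids: frozenset = dataclasses.field(default_factory=frozenset)

    def to_dict(self) -> dict:
        return {
            "n_detected_annotated": self.n_detected_annotated,
            "n_true_detected": self.n_true_detected,
            "n_identified_annotated": self.n_identified_annotated,
            "n_true_identified": self.n_true_identified,
            "ef": self.ef,
            "flags": list(self.flags),
        }


def enrichment_factor(n_true_identified: int, n_identified: int,
                      n_true_detected: int, n_detected: int) -> float:
    """(true rate among identified) / (true rate in the detected universe)."""
    if n_identified <= 0 or n_detected <= 0:
        raise ValueError("identified and detected totals must be > 0")
    if n_true_detected <= 0:
        raise ValueError("no true marker in the detected universe; "
                         "EF undefined")
    return (n_true_identified / n_identified) / (n_true_detected / n_detected)


def ef_report_from_sets(universe: frozenset, identified: frozenset,
                        truth: TrueMarkerSet) -> EFReport:
    """EF bookkeeping from metabolite-ID sets (identified ⊆ universe)."""
    identified = frozenset(identified) & frozenset(universe)
    true_detected = frozenset(universe) & truth.metabolite_ids
    true_identified = identified & truth.metabolite_ids
    flags: list[str] = []
    if not true_detected:
        logger.warning("truth disjoint from detected universe; EF undefined")
        return EFReport(len(universe), 0, len(identified),
                        len(true_identified), float("nan"),
                        flags=("undefined",),
                        universe_ids=frozenset(universe),
                        identified_ids=identified)
    if not identified:
        flags.append("no_identified_metabolites")
        ef = 0.0
    else:
        ef = enrichment_factor(len(true_identified), len(identified),
                               len(true_detected), len(universe))
    if len(true_identified) <= 1:
        flags.append("low_support")
    return EFReport(
        n_detected_annotated=len(universe),
        n_true_detected=len(true_detected),
        n_identified_annotated=len(identified),
        n_true_identified=len(true_identified),
        ef=ef,
        flags=tuple(flags),
        universe_ids=frozenset(universe),
        identified_ids=identified,
    )


def ef_report(markers: MarkerList, annotation: AnnotationResult,
              truth: TrueMarkerSet) -> EFReport:
    """EF of a marker list given the full detected-peak annotation."""
    identified = annotation.metabolites_for(markers.feature_keys)
    return ef_report_from_sets(annotation.universe, identified, truth)
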