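"""Direct-merge core: m/z-tolerance feature matching and table fusion.

Two experiments' feature lists are matched one-to-one on m/z alone
(retention time is deliberately ignored), greedily accepting candidate
pairs in order of increasing |Δm/z|.  The merged table keeps only the
common features and concatenates the two experiments' samples.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .io_formats import PeakTable, concat_samples

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MzTolerance:
    """Matching tolerance, in ppm (relative) or Da (absolute)."""

    value: float
    unit: str = "Da"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be > 0")
        if self.unit not in ("ppm", "Da"):
            raise ValueError("tolerance unit must be 'ppm' or 'Da'")

    def limit(self, mz_a: float, mz_b: float) -> float:
        """Absolute |Δm/z| limit for a candidate pair."""
        if self.unit == "Da":
            return self.value
        return self.value * 1e-6 * 0.5 * (mz_a + mz_b)


@dataclasses.dataclass
class MatchSet:
    """One-to-one feature matching between two experiments.

    ``pairs`` holds (index in A, index in B, Δm/z in Da); the unmatched
    lists complete the partition of both feature sets.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_features(mz_a: np.ndarray, mz_b: np.ndarray,
                   tol: MzTolerance) -> MatchSet:
    """Greedy minimum-|Δm/z| one-to-one matching within the tolerance.

    Candidate pairs within tolerance are ranked by |Δm/z| ascending (ties
    broken by lower index pair) and accepted when both endpoints are still
    unused.  Empty inputs yield an empty match set.
    """
    mz_a = np.asarray(mz_a, dtype=float)
    mz_b = np.asarray(mz_b, dtype=float)
    if mz_a.size == 0 or mz_b.size == 0:
        return MatchSet([], list(range(mz_a.size)), list(range(mz_b.size)))

    order_b = np.argsort(mz_b, kind="stable")
    sorted_b = mz_b[order_b]
    # widest possible window; ppm limit is pair-dependent so filter after
    if tol.unit == "Da":
        max_win = tol.value
    else:
        max_win = tol.value * 1e-6 * float(max(mz_a.max(), mz_b.max()))

    candidates: list[tuple[float, int, int]] = []
    for i, ma in enumerate(mz_a):
        lo = np.searchsorted(sorted_b, ma - max_win, side="left")
        hi = np.searchsorted(sorted_b, ma + max_win, side="right")
        for pos in range(lo, hi):
            j = int(order_b[pos])
            delta = abs(ma - mz_b[j])
            if delta <= tol.limit(ma, float(mz_b[j])):
                candidates.append((delta, i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for delta, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, float(mz_a[i] - mz_b[j])))
    pairs.sort()
    return MatchSet(
        pairs=pairs,
        unmatched_a=[i for i in range(mz_a.size) if i not in used_a],
        unmatched_b=[j for j in range(mz_b.size) if j not in used_b],
    )


def merge_tables(a: PeakTable, b: PeakTable, matches: MatchSet) -> PeakTable:
    """Build the merged common-feature table from a match set.

    Merged features keep the intensity-weighted mean m/z of each pair
    (arithmetic mean when weights tie or vanish) and the arithmetic mean
    RT; samples are the concatenation of both experiments, intensities
    and missingness carried over unchanged.
    """
    if matches.n_matched == 0:
        raise ValueError("no common features between the two experiments")
    ia = np.array([p[0] for p in matches.pairs])
    ib = np.array([p[1] for p in matches.pairs])

    wa = np.nansum(a.intensities[ia], axis=1)
    wb = np.nansum(b.intensities[ib], axis=1)
    wsum = wa + wb
    with np.errstate(invalid="ignore", divide="ignore"):
        mz = np.where(
            wsum > 0,
            (a.mz[ia] * wa + b.mz[ib] * wb) / np.where(wsum > 0, wsum, 1.0),
            0.5 * (a.mz[ia] + b.mz[ib]),
        )
    # equal observed m/z must survive merging bit-exactly (self-merge)
    same = a.mz[ia] == b.mz[ib]
    mz[same] = a.mz[ia][same]
    rt = 0.5 * (a.rt[ia] + b.rt[ib])

    sub_a = a.subset_features(ia)
    sub_b = b.subset_features(ib)
    sub_a.mz = mz.copy()
    sub_a.rt = rt.copy()
    sub_b.mz = mz.copy()
    sub_b.rt = rt.copy()
    return concat_samples(sub_a, sub_b)
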