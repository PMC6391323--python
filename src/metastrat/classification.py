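"""Classification-capacity criterion.

Stratified train/test/independent splitting, t-test feature selection on
train+test, RBF-SVM fitting with a small grid chosen on the test split,
and evaluation on the untouched independent split via confusion-matrix
metrics (SEN/SPE/ACC/MCC) and rank-based ROC AUC.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_formats import GROUP_CASE, PeakTable, concat_samples
from .markers import feature_pvalues

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.1, 1.0, 10.0)
DEFAULT_GAMMA_GRID = ("scale", 0.01, 0.1)


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class ClassificationMetrics:
    """SEN/SPE/ACC/MCC (NaN where undefined, with flags) plus AUC."""

    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float = math.nan
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def split_dataset(table: PeakTable, fractions: tuple[float, float, float],
                  seed: int) -> tuple[PeakTable, PeakTable, PeakTable]:
    """Stratified-by-group random partition into train/test/independent.

    Per-group split sizes follow the fractions with largest-remainder
    rounding, so 60/20/20 on 10+10 gives exactly 6/2/2 per group.  Splits
    with a positive fraction must receive at least one sample per group.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for group in sorted(set(table.groups)):
        idx = np.flatnonzero(table.groups == group)
        idx = rng.permutation(idx)
        n = idx.size
        raw = [f * n for f in fractions]
        counts = [int(math.floor(r)) for r in raw]
        remainders = [r - c for r, c in zip(raw, counts)]
        for _ in range(n - sum(counts)):
            j = int(np.argmax(remainders))
            counts[j] += 1
            remainders[j] = -1.0
        for j, f in enumerate(fractions):
            if f > 0 and counts[j] == 0:
                raise ValueError(
                    f"split {j} would get no {group!r} samples; "
                    "infeasible stratification"
                )
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[start:start + c].tolist())
            start += c
    return tuple(
        table.subset_samples(np.sort(np.array(p, dtype=int)))
        if p else _empty_subset(table)
        for p in parts
    )  # type: ignore[return-value]


def _empty_subset(table: PeakTable) -> PeakTable:
    """Zero-sample view; bypasses the case/control invariant on purpose."""
    out = table.copy()
    out.intensities = out.intensities[:, :0]
    out.sample_ids = []
    out.groups = out.groups[:0]
    out.experiments = out.experiments[:0]
    return out


def confusion_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """SEN, SPE, ACC and MCC from confusion counts.

    Metrics with a zero denominator are reported as NaN and listed in
    ``undefined`` rather than coerced to 0.
    """
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sen = ratio(c.tp, c.tp + c.fn, "sen")
    spe = ratio(c.tn, c.tn + c.fp, "spe")
    acc = ratio(c.tp + c.tn, c.total, "acc")
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = math.nan
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return ClassificationMetrics(sen=sen, spe=spe, acc=acc, mcc=mcc,
                                 undefined=tuple(undefined))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def fit_and_evaluate(
    train: PeakTable,
    test: PeakTable,
    independent: PeakTable,
    alpha: float = 0.05,
    c_grid: tuple = DEFAULT_C_GRID,
    gamma_grid: tuple = DEFAULT_GAMMA_GRID,
    return_scores: bool = False,
):
    """Select features on train+test, fit an RBF SVM, score the hold-out.

    Feature selection is the Student's t-test at ``alpha`` on the pooled
    train+test samples (falling back to all features, logged, if nothing
    passes).  Hyperparameters (C, gamma) are picked on the test split by
    accuracy; the model is then refit on train+test and evaluated on the
    independent split only.  Decision values feed the rank-based AUC.
    """
    pool = concat_samples(train, test)
    p = feature_pvalues(pool)
    sel = np.flatnonzero(p < alpha)
    if sel.size == 0:
        logger.warning("no feature passed t-test selection at alpha=%g; "
                       "using all features", alpha)
        sel = np.arange(pool.n_features)

    def design(t: PeakTable) -> tuple[np.ndarray, np.ndarray]:
        if np.isnan(t.intensities).any():
            raise ValueError("fit_and_evaluate requires pretreated tables")
        return t.intensities[sel].T, (t.groups == GROUP_CASE)

    x_train, y_train = design(train)
    x_test, y_test = design(test)
    x_pool, y_pool = design(pool)
    x_ind, y_ind = design(independent)
    if not (y_ind.any() and (~y_ind).any()):
        raise ValueError("independent split must contain both classes")

    if x_test.shape[0] > 0 and y_test.any() and (~y_test).any():
        best, best_acc = None, -1.0
        scaler = StandardScaler().fit(x_train)
        for cc in c_grid:
            for gg in gamma_grid:
                clf = SVC(C=cc, gamma=gg, kernel="rbf")
                clf.fit(scaler.transform(x_train), y_train)
                acc = float(
                    (clf.predict(scaler.transform(x_test)) == y_test).mean()
                )
                if acc > best_acc:
                    best, best_acc = (cc, gg), acc
        c_best, gamma_best = best
    else:
        logger.warning("test split unusable for hyperparameter choice; "
                       "using defaults C=1, gamma='scale'")
        c_best, gamma_best = 1.0, "scale"

    scaler = StandardScaler().fit(x_pool)
    model = SVC(C=c_best, gamma=gamma_best, kernel="rbf")
    model.fit(scaler.transform(x_pool), y_pool)

    x_ind_s = scaler.transform(x_ind)
    pred = model.predict(x_ind_s)
    scores = model.decision_function(x_ind_s)
    counts = ConfusionCounts(
        tp=int((pred & y_ind).sum()),
        tn=int((~pred & ~y_ind).sum()),
        fp=int((pred & ~y_ind).sum()),
        fn=int((~pred & y_ind).sum()),
    )
    metrics = confusion_metrics(counts)
    metrics.auc = roc_auc(scores, y_ind)
    if return_scores:
        return metrics, scores, y_ind
    return metrics
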