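"""End-to-end orchestration of the four analytical strategies.

SiE1/SiE2 analyze each experiment alone; DiMe matches and merges the two
experiments before a single joint analysis; ReIn runs both single-
experiment pipelines and integrates the results (metric averaging for
classification, pairwise overlap averaging for robustness, metabolite-set
intersection for the enrichment factor).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classification import (
    ClassificationMetrics,
    fit_and_evaluate,
    split_dataset,
)
from .io_formats import PeakTable, ReferenceLibrary, TrueMarkerSet
from .markers import annotate, plsda_markers
from .merging import MzTolerance, match_features, merge_tables
from .preprocessing import pretreat
from .stability_fdr import (
    EFReport,
    OverlapReport,
    compare_overlap_distributions,
    ef_report,
    ef_report_from_sets,
    integrate_robustness,
    robustness_report,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("SiE1", "SiE2", "ReIn", "DiMe")
_STAGE_IDS = {"split": 1, "robustness": 2}


@dataclasses.dataclass
class RunConfig:
    """Every threshold of the comparison, with the shipped defaults."""

    tol_value: float = 0.05
    tol_unit: str = "Da"
    k: int = 10
    n_components: int = 2
    vip_threshold: float = 1.0
    alpha: float = 0.05
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_iter: int = 10
    annot_ppm: float = 20.0
    mode: str = "positive"
    seed: int = 0

    def validate(self) -> None:
        MzTolerance(self.tol_value, self.tol_unit)  # validates value/unit
        if self.k < 1 or self.n_iter < 2 or self.n_components < 1:
            raise ValueError("k, n_iter, n_components out of range")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "split" in raw:
            raw["split"] = tuple(raw["split"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split"] = list(self.split)
        return d

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed only,
        so identical inputs give identical stage randomness everywhere."""
        ss = np.random.SeedSequence([int(self.seed), _STAGE_IDS[stage]])
        return int(ss.generate_state(1)[0])

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class StrategyReport:
    """Per-strategy bundle of the three evaluation criteria."""

    strategy: str
    classification: "ClassificationMetrics"
    robustness: OverlapReport
    ef: EFReport
    provenance: dict
    scores: np.ndarray | None = None
    score_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "classification": self.classification.to_dict(),
            "robustness": self.robustness.to_dict(),
            "ef": self.ef.to_dict(),
            "provenance": self.provenance,
        }


def _provenance(cfg: RunConfig, strategy: str) -> dict:
    return {
        "strategy": strategy,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }


def run_sie(exp: PeakTable, cfg: RunConfig, lib: ReferenceLibrary,
            truth: TrueMarkerSet, label: str = "SiE1") -> StrategyReport:
    """Single-experiment pipeline: pretreat, then all three criteria."""
    cfg.validate()
    pretreated = pretreat(exp, k=cfg.k)

    train, test, indep = split_dataset(pretreated, cfg.split,
                                       seed=cfg.stage_seed("split"))
    clf, scores, labels = fit_and_evaluate(
        train, test, indep, alpha=cfg.alpha, return_scores=True
    )
    rob = robustness_report(pretreated, n_iter=cfg.n_iter, alpha=cfg.alpha,
                            seed=cfg.stage_seed("robustness"))
    mk = plsda_markers(pretreated, vip_threshold=cfg.vip_threshold,
                       alpha=cfg.alpha, n_components=cfg.n_components)
    ann = annotate(pretreated.feature_keys, lib, tol_ppm=cfg.annot_ppm,
                   mode=cfg.mode)
    ef = ef_report(mk, ann, truth)
    return StrategyReport(
        strategy=label, classification=clf, robustness=rob, ef=ef,
        provenance=_provenance(cfg, label), scores=scores,
        score_labels=labels,
    )


def run_dime(a: PeakTable, b: PeakTable, cfg: RunConfig,
             lib: ReferenceLibrary, truth: TrueMarkerSet) -> StrategyReport:
    """Direct-merge pipeline: match, merge, pretreat, then criteria."""
    cfg.validate()
    matches = match_features(a.mz, b.mz,
                             MzTolerance(cfg.tol_value, cfg.tol_unit))
    merged = merge_tables(a, b, matches)
    report = run_sie(merged, cfg, lib, truth, label="DiMe")
    report.provenance["n_merged_features"] = matches.n_matched
    return report


def run_rein(a: PeakTable, b: PeakTable, cfg: RunConfig,
             lib: ReferenceLibrary, truth: TrueMarkerSet) -> StrategyReport:
    """Results-integration pipeline: per-experiment runs, then integration.

    Classification metrics are the arithmetic mean of the two experiments'
    metrics; robustness averages the pairwise overlap values; the EF uses
    the intersection of the two annotated universes and of the two
    identified-metabolite sets.
    """
    r1 = run_sie(a, cfg, lib, truth, label="SiE1")
    r2 = run_sie(b, cfg, lib, truth, label="SiE2")

    def mean_nan(x: float, y: float) -> float:
        if math.isnan(x) or math.isnan(y):
            return math.nan
        return 0.5 * (x + y)

    clf = ClassificationMetrics(
        sen=mean_nan(r1.classification.sen, r2.classification.sen),
        spe=mean_nan(r1.classification.spe, r2.classification.spe),
        acc=mean_nan(r1.classification.acc, r2.classification.acc),
        mcc=mean_nan(r1.classification.mcc, r2.classification.mcc),
        auc=mean_nan(r1.classification.auc, r2.classification.auc),
        undefined=tuple(sorted(set(r1.classification.undefined)
                               | set(r2.classification.undefined))),
    )
    rob = integrate_robustness(r1.robustness, r2.robustness)
    universe = r1.ef.universe_ids & r2.ef.universe_ids
    identified = r1.ef.identified_ids & r2.ef.identified_ids
    ef = ef_report_from_sets(universe, identified, truth)
    return StrategyReport(
        strategy="ReIn", classification=clf, robustness=rob, ef=ef,
        provenance=_provenance(cfg, "ReIn"),
    )


def compare_strategies(a: PeakTable, b: PeakTable, cfg: RunConfig,
                       lib: ReferenceLibrary, truth: TrueMarkerSet,
                       outdir: str | Path | None = None) -> dict:
    """Run all four strategies with shared seeds and bundle the comparison.

    Returns a dict with the four reports, the one-sided rank-sum p-values
    of the direct-merge overlap distribution against each other strategy,
    and full provenance.  When ``outdir`` is given, writes the JSON
    report, CSV summary tables and SVG figures there.
    """
    cfg.validate()
    reports = {
        "SiE1": run_sie(a, cfg, lib, truth, label="SiE1"),
        "SiE2": run_sie(b, cfg, lib, truth, label="SiE2"),
        "ReIn": run_rein(a, b, cfg, lib, truth),
        "DiMe": run_dime(a, b, cfg, lib, truth),
    }
    pvals = {}
    for other in ("SiE1", "SiE2", "ReIn"):
        p, degenerate = compare_overlap_distributions(
            reports["DiMe"].robustness.overlaps,
            reports[other].robustness.overlaps,
        )
        pvals[f"DiMe_gt_{other}"] = {"p_value": p, "degenerate": degenerate}
    result = {
        "reports": {k: v.to_dict() for k, v in reports.items()},
        "overlap_rank_sum": pvals,
        "provenance": _provenance(cfg, "comparison"),
    }
    if outdir is not None:
        _write_outputs(result, reports, Path(outdir))
    return result


def _write_outputs(result: dict, reports: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(result, fh, indent=2)

    rows = []
    for name, rep in reports.items():
        c, e = rep.classification, rep.ef
        rows.append({
            "strategy": name, "acc": c.acc, "sen": c.sen, "spe": c.spe,
            "mcc": c.mcc, "auc": c.auc,
            "median_overlap": rep.robustness.median_overlap,
            "total_markers": rep.robustness.total_identified,
            "n_identified_annotated": e.n_identified_annotated,
            "n_true_identified": e.n_true_identified,
            "ef": e.ef,
        })
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([reports[s].robustness.overlaps for s in STRATEGIES],
               tick_labels=list(STRATEGIES))
    ax.set_ylabel("overlap value")
    ax.set_title("Marker robustness across half-samplings")
    fig.tight_layout()
    fig.savefig(outdir / "overlap_boxplot.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for name in STRATEGIES:
        rep = reports[name]
        if rep.scores is None:
            continue
        order = np.argsort(-rep.scores)
        labels = rep.score_labels[order]
        tpr = np.concatenate([[0], np.cumsum(labels) / labels.sum()])
        fpr = np.concatenate([[0], np.cumsum(~labels) / (~labels).sum()])
        ax.plot(fpr, tpr, label=f"{name} (AUC={rep.classification.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "roc_curves.svg")
    plt.close(fig)
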