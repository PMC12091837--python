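"""Reference predictors and the split-sensitivity benchmark.

The harness does not ship deep TCR-binding models; its job is to show what
a splitting protocol can and cannot expose.  The *memorization* predictor —
score a test pair by the empirical positive rate of its peptide in the
training set, 0.5 if unseen — is the minimal model that exploits peptide
leakage.  On a random split it looks competent; on any peptide-disjoint
split every test peptide is unseen and its AUROC collapses to exactly 0.5.
External models can be plugged in through the same scorer interface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .dataset import InteractionDataset, InteractionRecord
from .errors import UndefinedMetricError
from .metrics import DistanceMatrix
from .split import (
    SplitAssignment,
    SplitConfig,
    cross_split_median_distance,
    distance_split,
    hard_split,
    random_split,
)

#: a scorer maps (peptide, cdr3b) to a score in [0, 1]
Scorer = Callable[[str, str], float]


def memorization_predictor(train_records: Sequence[InteractionRecord]) -> Scorer:
    """Peptide-level memorization baseline.

    Score = empirical positive rate of the pair's peptide among training
    records; 0.5 for peptides never seen in training.
    """
    if not train_records:
        raise ValueError("training records must be non-empty")
    pos: dict[str, int] = {}
    tot: dict[str, int] = {}
    for r in train_records:
        tot[r.peptide] = tot.get(r.peptide, 0) + 1
        pos[r.peptide] = pos.get(r.peptide, 0) + (1 if r.label == 1 else 0)
    rates = {p: pos[p] / tot[p] for p in tot}

    def score(peptide: str, cdr3b: str) -> float:
        return rates.get(peptide, 0.5)

    return score


def random_predictor(seed: int = 0) -> Scorer:
    """Uniform-random scores; the no-information baseline."""
    rng = np.random.default_rng(seed)

    def score(peptide: str, cdr3b: str) -> float:
        return float(rng.random())

    return score


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Probability that a uniformly random positive outscores a uniformly
    random negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: both classes required")
    ranks = stats.rankdata(scores)  # average ranks handle ties as half-wins
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


@dataclass(frozen=True)
class BenchmarkResult:
    """One predictor evaluation on one split realization."""

    split_label: str
    seed: int
    auroc: float
    n_test: int
    cross_split_median_distance: Optional[float] = None
    band_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0):
            raise ValueError("auroc must lie in [0, 1]")
        if self.n_test <= 0:
            raise ValueError("n_test must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """One split protocol to benchmark.

    ``kind`` is ``random``/``hard``/``distance``; ``metric`` and ``band``
    apply to distance splits only; ``band_index`` orders the bands for the
    trend analysis.
    """

    label: str
    kind: str
    metric: Optional[str] = None
    band: Optional[tuple[float, float]] = None
    band_index: Optional[int] = None


DEFAULT_BANDS = ((0.0, 33.0), (33.0, 66.0), (66.0, 100.0))


def default_split_specs(metrics: Iterable[str] = ("rmsd",)) -> list[SplitSpec]:
    """RS + HS + the three canonical DS bands per metric."""
    specs = [SplitSpec("RS", "random"), SplitSpec("HS", "hard")]
    for metric in metrics:
        for k, band in enumerate(DEFAULT_BANDS):
            specs.append(SplitSpec(
                f"DS-{metric}-({band[0]:g},{band[1]:g})", "distance",
                metric=metric, band=band, band_index=k,
            ))
    return specs


def _make_assignment(ds: InteractionDataset, spec: SplitSpec,
                     matrices: Mapping[str, DistanceMatrix],
                     cfg: SplitConfig) -> SplitAssignment:
    if spec.kind == "random":
        return random_split(ds, cfg)
    if spec.kind == "hard":
        return hard_split(ds, cfg)
    if spec.kind == "distance":
        if spec.metric not in matrices:
            raise ValueError(f"no distance matrix for metric {spec.metric!r}")
        band_cfg = SplitConfig(
            ratios=cfg.ratios, band=spec.band, min_count=cfg.min_count,
            max_count=cfg.max_count, seed=cfg.seed, aggregator=cfg.aggregator,
        )
        return distance_split(ds, matrices[spec.metric], band_cfg)
    raise ValueError(f"unknown split kind {spec.kind!r}")


def evaluate_split(ds: InteractionDataset, assignment: SplitAssignment,
                   predictor_factory: Callable[[Sequence[InteractionRecord]], Scorer]
                   = memorization_predictor) -> tuple[float, int]:
    """Train the predictor on the train partition, score the test partition,
    return (AUROC, n_test)."""
    train = [ds.records[i] for i in assignment.train]
    test = [ds.records[i] for i in assignment.test]
    scorer = predictor_factory(train)
    scores = [scorer(r.peptide, r.cdr3b) for r in test]
    labels = [r.label for r in test]
    return auroc(scores, labels), len(test)


def spearman_trend(band_indices: Sequence[int],
                   aurocs: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation between band index and AUROC.

    The p-value is an exact two-sided permutation p for up to 8 points and
    the asymptotic approximation above that.
    """
    import warnings

    x = np.asarray(band_indices, dtype=float)
    y = np.asarray(aurocs, dtype=float)
    if len(x) < 3:
        raise ValueError("trend needs at least 3 points")
    with warnings.catch_warnings():
        # constant AUROCs (e.g. an all-fallback predictor) are a valid null
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p_asym = stats.spearmanr(x, y)
    if np.isnan(rho):  # constant input
        return 0.0, 1.0
    n = len(x)
    if n <= 8:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r, _ = stats.pearsonr(rx, np.asarray(perm))
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return float(rho), count / total
    return float(rho), float(p_asym)


def summarize(results: Sequence[BenchmarkResult]) -> dict:
    """Per-split mean AUROC with a normal-approximation 95% CI, plus the
    Spearman band-index/AUROC trend over distance splits (per metric)."""
    by_label: dict[str, list[BenchmarkResult]] = {}
    for r in results:
        by_label.setdefault(r.split_label, []).append(r)

    summary: dict = {"splits": {}, "trend": {}}
    for label, rs in by_label.items():
        vals = np.array([r.auroc for r in rs], dtype=float)
        k = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if k > 1 else 0.0
        half = 1.96 * sd / math.sqrt(k) if k > 1 else 0.0
        dists = [r.cross_split_median_distance for r in rs
                 if r.cross_split_median_distance is not None]
        summary["splits"][label] = {
            "mean_auroc": mean,
            "ci95": [mean - half, mean + half],
            "sd": sd,
            "n_seeds": k,
            "mean_cross_split_median_distance":
                float(np.mean(dists)) if dists else None,
        }

    # trend per metric over DS results
    ds_results = [r for r in results
                  if r.band_index is not None and r.split_label.count("-") >= 2]
    metrics = sorted({r.split_label.split("-")[1] for r in ds_results})
    for metric in metrics:
        pts = [r for r in ds_results if r.split_label.split("-")[1] == metric]
        if len(pts) >= 3 and len({r.band_index for r in pts}) >= 2:
            rho, p = spearman_trend([r.band_index for r in pts],
                                    [r.auroc for r in pts])
            summary["trend"][metric] = {"spearman_rho": rho, "p_value": p,
                                        "n_points": len(pts)}
    return summary


def run_benchmark(
    ds: InteractionDataset,
    matrices: Mapping[str, DistanceMatrix],
    split_specs: Sequence[SplitSpec],
    seeds: Sequence[int],
    predictor_factory: Callable[[Sequence[InteractionRecord]], Scorer]
    = memorization_predictor,
    base_config: Optional[SplitConfig] = None,
) -> tuple[list[BenchmarkResult], dict]:
    """Evaluate the predictor on every split spec x seed.

    Pooled AUROC is computed per realization; the summary reports per-split
    means with 95% CIs and the band/AUROC Spearman trend.
    """
    base = base_config or SplitConfig()
    results: list[BenchmarkResult] = []
    for spec in split_specs:
        for seed in seeds:
            cfg = SplitConfig(
                ratios=base.ratios, band=base.band, min_count=base.min_count,
                max_count=base.max_count, seed=int(seed),
                aggregator=base.aggregator,
            )
            assignment = _make_assignment(ds, spec, matrices, cfg)
            score, n_test = evaluate_split(ds, assignment, predictor_factory)
            cross = None
            if spec.metric is not None and spec.metric in matrices:
                cross = cross_split_median_distance(assignment, ds,
                                                    matrices[spec.metric])
            results.append(BenchmarkResult(
                split_label=spec.label, seed=int(seed), auroc=score,
                n_test=n_test, cross_split_median_distance=cross,
                band_index=spec.band_index,
            ))
    return results, summarize(results)
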