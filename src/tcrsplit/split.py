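"""Train/validation/test splitting: random, hard, and distance-controlled.

Three protocols of increasing stringency:

* **Random split (RS)** — record-level permutation; the same peptide can
  appear on both sides of the train/test boundary, so a model may score well
  by memorizing peptides.
* **Hard split (HS)** — peptide-level sampling; every record of a peptide
  lands in exactly one of train/validation/test, so test peptides are never
  observed at training time.
* **Distance split (DS)** — like HS, but test and validation peptides are
  drawn only from a percentile band of the per-peptide aggregated distance
  distribution, which controls how far the held-out peptides sit from the
  rest of the dataset.  Band (0, 33) holds out typical peptides; (66, 100)
  holds out outliers.

Splits are budgeted by record counts (positives and negatives alike) from
the configured ratios; peptides move atomically, so the last peptide drawn
may overshoot a budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .dataset import InteractionDataset, write_interaction_table
from .errors import InfeasibleBandError, InfeasibleError
from .metrics import (
    AGGREGATORS,
    AggregatedDistanceVector,
    DistanceMatrix,
    aggregate_rowwise,
)

SPLIT_NAMES = ("train", "validation", "test")


@dataclass(frozen=True)
class SplitConfig:
    """Parameters shared by all split protocols.

    ``band``, ``min_count``, ``max_count`` and ``aggregator`` only matter for
    the distance split; the defaults are a 90-5-5 ratio, the full (0, 100)
    band, and peptide count bounds of 5 to 5000.
    """

    ratios: tuple[float, float, float] = (0.90, 0.05, 0.05)
    band: tuple[float, float] = (0.0, 100.0)
    min_count: int = 5
    max_count: int = 5000
    seed: int = 0
    aggregator: str = "median"

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive numbers")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")
        bl, bu = self.band
        if not (0 <= bl < bu <= 100):
            raise ValueError(f"band must satisfy 0 <= lower < upper <= 100, got {self.band}")
        if not (1 <= self.min_count <= self.max_count):
            raise ValueError("require 1 <= min_count <= max_count")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


@dataclass(frozen=True)
class SplitAssignment:
    """Partition of record indices with the provenance that produced it."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    budgets: dict  # {"train": N_train, "validation": ..., "test": ...}
    seed: int
    method: str  # "random" | "hard" | "distance"
    band_bounds: Optional[tuple[float, float]] = None  # realized (d_l, d_u)
    band: Optional[tuple[float, float]] = None  # requested percentiles
    metric: Optional[str] = None
    aggregator: Optional[str] = None

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/validation/test index sets must be disjoint")

    @property
    def realized_counts(self) -> dict:
        return {
            "train": len(self.train),
            "validation": len(self.validation),
            "test": len(self.test),
        }

    def split_peptides(self, ds: InteractionDataset, which: str) -> set[str]:
        idx = getattr(self, which)
        return {ds.records[i].peptide for i in idx}

    def manifest(self) -> dict:
        out = {
            "method": self.method,
            "seed": self.seed,
            "budgets": self.budgets,
            "realized_counts": self.realized_counts,
        }
        if self.band is not None:
            out["band"] = list(self.band)
        if self.band_bounds is not None:
            out["band_bounds"] = list(self.band_bounds)
        if self.metric is not None:
            out["metric"] = self.metric
        if self.aggregator is not None:
            out["aggregator"] = self.aggregator
        return out


def _budgets(n_records: int, ratios: tuple[float, float, float]) -> dict:
    n_train = int(round(ratios[0] * n_records))
    n_val = int(round(ratios[1] * n_records))
    n_test = int(round(ratios[2] * n_records))
    return {"train": n_train, "validation": n_val, "test": n_test}


def percentile_bounds(v: AggregatedDistanceVector,
                      band: tuple[float, float]) -> tuple[float, float]:
    """Distances at the band's percentiles (linear interpolation between
    closest ranks)."""
    bl, bu = band
    if not (0 <= bl < bu <= 100):
        raise ValueError(f"invalid percentile band {band}")
    if len(v.peptides) < 2:
        raise ValueError("need at least 2 peptides")
    d_l, d_u = np.percentile(v.values, [bl, bu], method="linear")
    return float(d_l), float(d_u)


def eligible_peptides(v: AggregatedDistanceVector,
                      bounds: tuple[float, float],
                      counts, min_count: int, max_count: int) -> set[str]:
    """Peptides inside the distance band whose record count lies in
    [min_count, max_count]."""
    d_l, d_u = bounds
    missing = [p for p in v.peptides if p not in counts]
    if missing:
        raise ValueError(f"counts missing for peptides, e.g. {missing[:3]}")
    return {
        p for p, d in zip(v.peptides, v.values)
        if d_l <= d <= d_u and min_count <= counts[p] <= max_count
    }


def _records_by_peptide(ds: InteractionDataset) -> dict[str, list[int]]:
    by: dict[str, list[int]] = {}
    for i, r in enumerate(ds.records):
        by.setdefault(r.peptide, []).append(i)
    return by


def _draw_peptides(pool: list[str], by_peptide: dict[str, list[int]],
                   budget: int, rng: np.random.Generator,
                   label: str, method: str) -> list[int]:
    """Draw whole peptides from *pool* (mutated) until *budget* records."""
    taken: list[int] = []
    while len(taken) < budget:
        if not pool:
            shortfall = budget - len(taken)
            exc_type = InfeasibleBandError if method == "distance" else InfeasibleError
            raise exc_type(
                f"peptide pool exhausted while filling the {label} set: "
                f"{shortfall} of {budget} records short"
            )
        k = int(rng.integers(len(pool)))
        peptide = pool.pop(k)
        taken.extend(by_peptide[peptide])
    return taken


def random_split(ds: InteractionDataset, cfg: SplitConfig) -> SplitAssignment:
    """Record-level uniform permutation cut at the ratio boundaries."""
    n = len(ds)
    if n < 3:
        raise ValueError("random_split requires at least 3 records")
    budgets = _budgets(n, cfg.ratios)
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_test, n_val = budgets["test"], budgets["validation"]
    test = perm[:n_test]
    validation = perm[n_test:n_test + n_val]
    train = perm[n_test + n_val:]
    return SplitAssignment(
        train=tuple(int(i) for i in train),
        validation=tuple(int(i) for i in validation),
        test=tuple(int(i) for i in test),
        budgets=budgets, seed=cfg.seed, method="random",
    )


def hard_split(ds: InteractionDataset, cfg: SplitConfig) -> SplitAssignment:
    """Peptide-disjoint split: whole peptides drawn into test, then
    validation, until the record budgets are met; the rest train."""
    peptides = list(ds.unique_peptides)
    if len(peptides) < 3:
        raise InfeasibleError("hard_split requires at least 3 unique peptides")
    budgets = _budgets(len(ds), cfg.ratios)
    rng = np.random.default_rng(cfg.seed)
    by_peptide = _records_by_peptide(ds)
    pool = sorted(peptides)
    test = _draw_peptides(pool, by_peptide, budgets["test"], rng, "test", "hard")
    validation = _draw_peptides(pool, by_peptide, budgets["validation"], rng,
                                "validation", "hard")
    assigned = set(test) | set(validation)
    train = [i for i in range(len(ds)) if i not in assigned]
    return SplitAssignment(
        train=tuple(train), validation=tuple(validation), test=tuple(test),
        budgets=budgets, seed=cfg.seed, method="hard",
    )


def distance_split(ds: InteractionDataset, m: DistanceMatrix,
                   cfg: SplitConfig) -> SplitAssignment:
    """Peptide-disjoint split constrained to a percentile band of the
    aggregated peptide distance distribution.

    Test peptides are drawn uniformly without replacement from the eligible
    in-band pool until the test record budget is reached (whole peptides,
    overshoot allowed); validation follows from the remaining in-band pool;
    everything else is train.  Raises :class:`InfeasibleBandError` when the
    pool empties before a budget is met, rather than silently relaxing the
    band.
    """
    ds_peptides = set(ds.unique_peptides)
    missing = ds_peptides - set(m.peptides)
    if missing:
        raise ValueError(
            f"distance matrix lacks {len(missing)} dataset peptides, "
            f"e.g. {sorted(missing)[:3]}"
        )
    budgets = _budgets(len(ds), cfg.ratios)
    v = aggregate_rowwise(m, cfg.aggregator)
    d_l, d_u = percentile_bounds(v, cfg.band)
    eligible = eligible_peptides(v, (d_l, d_u), ds.peptide_counts | {
        p: 0 for p in m.peptides if p not in ds.peptide_counts
    }, cfg.min_count, cfg.max_count)
    eligible &= ds_peptides
    if not eligible:
        raise InfeasibleBandError(
            f"no eligible peptides in band {cfg.band} with counts in "
            f"[{cfg.min_count}, {cfg.max_count}]"
        )
    rng = np.random.default_rng(cfg.seed)
    by_peptide = _records_by_peptide(ds)
    pool = sorted(eligible)
    test = _draw_peptides(pool, by_peptide, budgets["test"], rng, "test", "distance")
    validation = _draw_peptides(pool, by_peptide, budgets["validation"], rng,
                                "validation", "distance")
    assigned = set(test) | set(validation)
    train = [i for i in range(len(ds)) if i not in assigned]
    return SplitAssignment(
        train=tuple(train), validation=tuple(validation), test=tuple(test),
        budgets=budgets, seed=cfg.seed, method="distance",
        band_bounds=(d_l, d_u), band=cfg.band, metric=m.metric,
        aggregator=cfg.aggregator,
    )


def cross_split_median_distance(assignment: SplitAssignment,
                                ds: InteractionDataset,
                                m: DistanceMatrix) -> float:
    """Median pairwise distance between train peptides and test peptides."""
    train_peps = sorted(assignment.split_peptides(ds, "train"))
    test_peps = sorted(assignment.split_peptides(ds, "test"))
    if not train_peps or not test_peps:
        raise ValueError("both train and test must contain peptides")
    return float(np.median(m.submatrix(train_peps, test_peps)))


def write_split(assignment: SplitAssignment, ds: InteractionDataset,
                outdir: str | Path) -> Path:
    """Write three canonical record tables plus a JSON manifest."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in SPLIT_NAMES:
        idx = getattr(assignment, name)
        subset = InteractionDataset(records=tuple(ds.records[i] for i in idx))
        write_interaction_table(subset, outdir / f"{name}.tsv")
    manifest = assignment.manifest() | {"tool": "tcrsplit", "version": __version__}
    (outdir / "split_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return outdir
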