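"""Internucleotide and structure-model analytics.

Filtering of interaction records (statistic bounds, correlation sign,
confidence class, region, 3D contact distance, top-k), base-pair model
comparison (correct / incorrect / missing with sensitivity and PPV),
multi-model consensus tables, 3D contact distances, distance histograms
and positional density heatmaps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import InteractionSet, SecondaryStructure, TertiaryStructure
from .errors import AnalysisError


@dataclass
class DistanceParams:
    """Atom used for 3D contact distances, with a fallback when absent."""

    atom: str = "O2'"
    fallback: str = "C1'"


@dataclass
class FilterCriteria:
    """Conjunctive record filter for an InteractionSet.

    ``bounds`` maps a statistic name to (min, max); None relaxes that side.
    ``sign`` restricts the sign of the set's default statistic.  Distance
    bounds (Angstrom) require a TertiaryStructure.  ``top_k`` keeps the k
    largest records by ``rank_by`` (default: the set's default statistic)
    among those passing everything else.
    """

    bounds: dict[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict)
    sign: str = "any"              # positive | negative | any
    class_label: str = "any"       # primary | secondary | any
    region: Optional[tuple[int, int]] = None
    min_distance: Optional[float] = None
    max_distance: Optional[float] = None
    top_k: Optional[int] = None
    rank_by: Optional[str] = None
    distance_params: DistanceParams = field(default_factory=DistanceParams)


def contact_distance(tertiary: TertiaryStructure, i: int, j: int,
                     params: DistanceParams | None = None) -> float:
    """Euclidean distance (Angstrom) between the chosen atoms of two
    transcript positions; NaN when an endpoint has neither atom."""
    params = params or DistanceParams()
    a, _ = tertiary.atom_xyz(i, params.atom, params.fallback)
    b, _ = tertiary.atom_xyz(j, params.atom, params.fallback)
    if a is None or b is None:
        return np.nan
    return float(np.linalg.norm(a - b))


def interaction_distances(iset: InteractionSet, tertiary: TertiaryStructure,
                          params: DistanceParams | None = None) -> np.ndarray:
    return np.array([
        contact_distance(tertiary, int(row["i"]), int(row["j"]), params)
        for _, row in iset.data.iterrows()
    ])


def filter_interactions(iset: InteractionSet, criteria: FilterCriteria,
                        tertiary: TertiaryStructure | None = None) -> int:
    """Update the set's mask in place; returns the pass count.

    Criteria compose conjunctively; applying the same criteria twice leaves
    the mask unchanged (the mask is recomputed from scratch each call).
    """
    df = iset.data
    mask = np.ones(len(df), dtype=bool)
    for name, (lo, hi) in criteria.bounds.items():
        if name not in df.columns:
            raise AnalysisError(
                f"unknown statistic {name!r}; available: {iset.statistic_names}"
            )
        col = df[name].to_numpy(float)
        if lo is not None:
            mask &= col >= lo
        if hi is not None:
            mask &= col <= hi
    if criteria.sign != "any":
        metric = criteria.rank_by or iset.default_metric
        if metric is None or metric not in df.columns:
            raise AnalysisError(
                f"sign filter needs a statistic; available: {iset.statistic_names}"
            )
        col = df[metric].to_numpy(float)
        mask &= (col > 0) if criteria.sign == "positive" else (col < 0)
    if criteria.class_label != "any":
        if "class_label" not in df.columns:
            raise AnalysisError("records carry no class labels")
        mask &= (df["class_label"] == criteria.class_label).to_numpy()
    if criteria.region is not None:
        lo, hi = criteria.region
        mask &= ((df["i"] >= lo) & (df["j"] <= hi)).to_numpy()
    if criteria.min_distance is not None or criteria.max_distance is not None:
        if tertiary is None:
            raise AnalysisError("distance criteria require a tertiary structure")
        dist = interaction_distances(iset, tertiary, criteria.distance_params)
        ok = np.isfinite(dist)
        if criteria.min_distance is not None:
            ok &= dist >= criteria.min_distance
        if criteria.max_distance is not None:
            ok &= dist <= criteria.max_distance
        mask &= ok
    if criteria.top_k is not None:
        metric = criteria.rank_by or iset.default_metric
        if metric is None or metric not in df.columns:
            raise AnalysisError(
                f"top_k needs a statistic; available: {iset.statistic_names}"
            )
        col = df[metric].to_numpy(float)
        passing = np.flatnonzero(mask)
        order = passing[np.argsort(-col[passing], kind="stable")]
        keep = set(order[: criteria.top_k])
        mask = np.array([k in keep for k in range(len(df))])
    iset.mask = mask
    return int(mask.sum())


@dataclass
class PairClassification:
    """Fig-style classification of a predicted pair set against an accepted
    one: correct = predicted and accepted, incorrect = predicted only,
    missing = accepted only."""

    correct: set[tuple[int, int]]
    incorrect: set[tuple[int, int]]
    missing: set[tuple[int, int]]

    @property
    def counts(self) -> dict[str, int]:
        return {"correct": len(self.correct), "incorrect": len(self.incorrect),
                "missing": len(self.missing)}

    @property
    def sensitivity(self) -> float:
        denom = len(self.correct) + len(self.missing)
        return len(self.correct) / denom if denom else np.nan

    @property
    def ppv(self) -> float:
        denom = len(self.correct) + len(self.incorrect)
        return len(self.correct) / denom if denom else np.nan


def classify_pairs(predicted: SecondaryStructure,
                   accepted: SecondaryStructure,
                   slip: int = 0) -> PairClassification:
    """Set algebra on two pair sets (same or pre-mapped sequences).

    ``slip`` > 0 lets a predicted pair count as correct when an accepted
    pair lies within +-slip at either endpoint; off by default.
    """
    if not predicted.sequence.matches(accepted.sequence):
        raise AnalysisError(
            f"structures are on different sequences "
            f"({predicted.sequence.id!r} vs {accepted.sequence.id!r})"
        )
    pred, acc = predicted.pairs, accepted.pairs
    if slip == 0:
        correct = pred & acc
        return PairClassification(correct=correct, incorrect=pred - correct,
                                  missing=acc - correct)
    def near(p, pool):
        return any(abs(p[0] - q[0]) <= slip and abs(p[1] - q[1]) <= slip
                   for q in pool)
    correct = {p for p in pred if near(p, acc)}
    missing = {q for q in acc if not near(q, pred)}
    return PairClassification(correct=correct, incorrect=pred - correct,
                              missing=missing)


@dataclass
class ConsensusTable:
    """Support counts for the union of pairs across k models."""

    support: dict[tuple[int, int], int]
    n_models: int
    min_support: int

    @property
    def union(self) -> set[tuple[int, int]]:
        return set(self.support)

    @property
    def consensus(self) -> set[tuple[int, int]]:
        return {p for p, s in self.support.items() if s >= self.min_support}

    @property
    def shared_by_all(self) -> set[tuple[int, int]]:
        return {p for p, s in self.support.items() if s == self.n_models}

    @property
    def fraction_shared_by_all(self) -> float:
        return len(self.shared_by_all) / len(self.support) if self.support else np.nan


def consensus_pairs(models: list[SecondaryStructure],
                    min_support: int = 3) -> ConsensusTable:
    """Count, over the union of all models' pairs, how many models predict
    each pair.  The fraction shared by all uses the union as denominator."""
    if len(models) < 2:
        raise AnalysisError(f"consensus needs >= 2 models, got {len(models)}")
    counter: Counter = Counter()
    for model in models:
        counter.update(model.pairs)
    return ConsensusTable(support=dict(counter), n_models=len(models),
                          min_support=min_support)


def distance_histogram(iset: InteractionSet, tertiary: TertiaryStructure,
                       bins=None, gap: int = 10,
                       params: DistanceParams | None = None):
    """Histogram of masked-in interaction contact distances plus a
    background histogram of all (i, j) distances with j > i + gap.

    Returns (counts, background_counts, bin_edges).  An empty mask gives a
    zero histogram, not an error.
    """
    params = params or DistanceParams()
    positions = sorted(tertiary.mapped_positions())
    bg = []
    for a_idx, i in enumerate(positions):
        for j in positions[a_idx + 1:]:
            if j > i + gap:
                d = contact_distance(tertiary, i, j, params)
                if np.isfinite(d):
                    bg.append(d)
    fg = [
        d for d, keep in zip(interaction_distances(iset, tertiary, params),
                             iset.mask)
        if keep and np.isfinite(d)
    ]
    if bins is None:
        top = max(bg + fg, default=1.0)
        bins = np.arange(0, top + 5.0, 5.0)
    counts, edges = np.histogram(fg, bins=bins)
    bg_counts, _ = np.histogram(bg, bins=edges)
    return counts, bg_counts, edges


def density_heatmap(iset: InteractionSet, bin_size: int = 10) -> np.ndarray:
    """Accumulate masked-in records into square (i, j) bins.

    Upper-triangular matrix (i-bin <= j-bin); total mass equals the filter
    pass count.
    """
    if bin_size < 1:
        raise AnalysisError(f"bin_size must be >= 1, got {bin_size}")
    n_bins = iset.sequence.length // bin_size + 1
    grid = np.zeros((n_bins, n_bins))
    for (i, j), keep in zip(iset.data[["i", "j"]].to_numpy(int), iset.mask):
        if keep:
            grid[i // bin_size, j // bin_size] += 1
    return grid
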