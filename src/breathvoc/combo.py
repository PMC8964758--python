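"""VOC-subset search: score compound combinations by leave-one-out CV and
rank them by accuracy, sensitivity and specificity.

A literal exhaustive search over all 6-of-64 subsets with LOO CV inside is
computationally implausible (~7.5×10⁷ subsets, each costing n classifier
fits), so three strategies are offered: ``exhaustive`` (budget-guarded, the
oracle at desk scale), ``greedy`` forward selection, and ``beam`` search.
Ranking ties break deterministically: primary metric descending, then the
other two metrics descending, then lexicographic compound-name order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classify import ClassifierConfig, CVMetrics, loo_evaluate

__all__ = [
    "ComboResult",
    "SearchPlan",
    "ComboSearch",
    "search_combinations",
    "metric_vs_k_curve",
    "top10_tables",
    "voc_frequency",
    "select_k",
]

_METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class ComboResult:
    """One scored VOC subset."""

    vocs: tuple[str, ...]
    metrics: CVMetrics

    def __post_init__(self) -> None:
        if not self.vocs or len(set(self.vocs)) != len(self.vocs):
            raise ValueError("VOC subset must be nonempty without duplicates")

    def metric(self, key: str) -> float:
        return getattr(self.metrics, key)

    def to_record(self) -> dict:
        return {
            "vocs": "|".join(self.vocs),
            "k": len(self.vocs),
            **{m: self.metric(m) for m in _METRICS},
        }


def _sort_key(result: ComboResult, rank_by: str):
    # primary metric, then the other two, then the held-out decision margin
    # (exact metric ties are common on separable panels and the margin still
    # carries information), then name order for full determinism
    others = [m for m in _METRICS if m != rank_by]
    return (
        -result.metric(rank_by),
        -result.metric(others[0]),
        -result.metric(others[1]),
        -(result.metrics.mean_margin or 0.0),
        tuple(sorted(result.vocs)),
    )


@dataclass(frozen=True)
class SearchPlan:
    """What to search and how.

    ``k`` may be an int or a (lo, hi) inclusive range. ``budget`` caps the
    number of subsets an exhaustive enumeration may evaluate.
    """

    pool: tuple[str, ...]
    k: int | tuple[int, int] = 6
    strategy: str = "exhaustive"
    budget: int = 200_000
    beam_width: int = 5
    rank_by: str = "accuracy"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def validate(self) -> None:
        if not self.pool or len(set(self.pool)) != len(self.pool):
            raise ValueError("pool must be nonempty without duplicates")
        if self.strategy not in ("exhaustive", "greedy", "beam"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.rank_by not in _METRICS:
            raise ValueError(f"rank_by must be one of {_METRICS}")
        if self.budget < 1 or self.beam_width < 1:
            raise ValueError("budget and beam_width must be >= 1")
        lo, hi = self.k_range
        if not 1 <= lo <= hi <= len(self.pool):
            raise ValueError("k out of range for the pool")

    @property
    def k_range(self) -> tuple[int, int]:
        return (self.k, self.k) if isinstance(self.k, int) else tuple(self.k)  # type: ignore[return-value]


class ComboSearch(BaseEstimator):
    """Estimator facade: ``fit(X, y)`` runs the plan, ``results_`` holds the
    ranked :class:`ComboResult` list."""

    def __init__(self, plan: SearchPlan = None, smote_subgroups=None,
                 positive_label="hcc"):
        self.plan = plan
        self.smote_subgroups = smote_subgroups
        self.positive_label = positive_label

    def _score(self, X: pd.DataFrame, pos, subset: tuple[str, ...]) -> ComboResult:
        metrics = loo_evaluate(
            X[list(subset)].to_numpy(),
            pos,
            config=self._config,
            positive_label=True,
            smote_subgroups=self.smote_subgroups,
        )
        return ComboResult(vocs=tuple(subset), metrics=metrics)

    def fit(self, X: pd.DataFrame, y):
        plan = self.plan
        plan.validate()
        missing = [v for v in plan.pool if v not in X.columns]
        if missing:
            raise ValueError(f"pool VOCs not in table: {missing}")
        self._config = replace(plan.classifier, seed=plan.seed)
        pos = np.asarray(y) == self.positive_label
        lo, hi = plan.k_range
        pool = tuple(plan.pool)

        results: list[ComboResult] = []
        if plan.strategy == "exhaustive":
            total = sum(math.comb(len(pool), k) for k in range(lo, hi + 1))
            if total > plan.budget:
                raise ValueError(
                    f"exhaustive enumeration of {total} subsets exceeds budget "
                    f"{plan.budget}; use strategy='greedy' or 'beam', or shrink the pool"
                )
            for k in range(lo, hi + 1):
                for subset in itertools.combinations(pool, k):
                    results.append(self._score(X, pos, subset))
        elif plan.strategy == "greedy":
            chosen: tuple[str, ...] = ()
            for _ in range(hi):
                candidates = [
                    self._score(X, pos, chosen + (v,)) for v in pool if v not in chosen
                ]
                best = min(candidates, key=lambda r: _sort_key(r, plan.rank_by))
                chosen = best.vocs
                if len(chosen) >= lo:
                    results.extend(candidates)
        else:  # beam
            frontier: list[tuple[str, ...]] = [()]
            for depth in range(hi):
                scored: list[ComboResult] = []
                seen: set[tuple[str, ...]] = set()
                for prefix in frontier:
                    for v in pool:
                        if v in prefix:
                            continue
                        subset = tuple(sorted(prefix + (v,)))
                        if subset in seen:
                            continue
                        seen.add(subset)
                        scored.append(self._score(X, pos, subset))
                scored.sort(key=lambda r: _sort_key(r, plan.rank_by))
                frontier = [r.vocs for r in scored[: plan.beam_width]]
                if depth + 1 >= lo:
                    results.extend(scored)

        self.results_ = sorted(results, key=lambda r: _sort_key(r, plan.rank_by))
        return self

    # -- reports -----------------------------------------------------------
    def top_tables(self, top: int = 10) -> dict[str, list[ComboResult]]:
        return top10_tables(self.results_, top=top)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_record() for r in self.results_])


def search_combinations(X: pd.DataFrame, y, plan: SearchPlan,
                        smote_subgroups=None, positive_label="hcc") -> list[ComboResult]:
    """Run ``plan`` on training data and return ranked results."""
    search = ComboSearch(plan=plan, smote_subgroups=smote_subgroups,
                         positive_label=positive_label)
    return search.fit(X, y).results_


def metric_vs_k_curve(X: pd.DataFrame, y, plan: SearchPlan,
                      smote_subgroups=None, positive_label="hcc") -> pd.DataFrame:
    """Best achievable accuracy/sensitivity/specificity per subset size k.

    Feeds the model-size selection step (smallest k with maximal accuracy
    and sensitivity at near-maximal specificity).
    """
    results = search_combinations(X, y, plan, smote_subgroups, positive_label)
    rows = []
    lo, hi = plan.k_range
    for k in range(lo, hi + 1):
        at_k = [r for r in results if len(r.vocs) == k]
        if not at_k:
            continue
        row = {"k": k}
        for m in _METRICS:
            best = min(at_k, key=lambda r: _sort_key(r, m))
            row[f"best_{m}"] = best.metric(m)
            row[f"best_{m}_vocs"] = "|".join(best.vocs)
        rows.append(row)
    return pd.DataFrame(rows)


def top10_tables(results: list[ComboResult], top: int = 10) -> dict[str, list[ComboResult]]:
    """The three ranked tables (by accuracy, sensitivity, specificity)."""
    if not results:
        raise ValueError("no results to rank")
    return {m: sorted(results, key=lambda r: _sort_key(r, m))[:top] for m in _METRICS}


def voc_frequency(tables: dict[str, list[ComboResult]]) -> dict[str, pd.Series]:
    """Appearance counts of each VOC across a key's top combinations,
    sorted descending (compounds with zero appearances omitted)."""
    out = {}
    for key, ranked in tables.items():
        counts: dict[str, int] = {}
        for r in ranked:
            for v in r.vocs:
                counts[v] = counts.get(v, 0) + 1
        ser = pd.Series(counts, dtype=int)
        out[key] = ser.sort_values(ascending=False, kind="stable")
    return out


def select_k(curve: pd.DataFrame, specificity_margin: float = 0.05) -> int:
    """Model-size rule: smallest k attaining the maximal accuracy and
    sensitivity among such k, provided its specificity is within
    ``specificity_margin`` of the specificity maximum over all k."""
    best_acc = curve["best_accuracy"].max()
    best_spec = curve["best_specificity"].max()
    at_max = curve[curve["best_accuracy"] >= best_acc - 1e-12]
    at_max = at_max.sort_values(["best_sensitivity", "k"], ascending=[False, True])
    for _, row in at_max.iterrows():
        if row["best_specificity"] >= best_spec - specificity_margin:
            return int(row["k"])
    return int(at_max.iloc[0]["k"])
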