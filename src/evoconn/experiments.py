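"""Result-generating procedures over subset searches.

These orchestrate the reporting analyses: the accuracy-versus-subset-size
curve (one search per cardinality k), its +/-20-point moving average, the
elementwise superiority of a search curve over the statistical baseline,
per-feature selection-frequency profiles with cumulative unique-feature
counts, and a most-indicative-feature report.

Per-k seeds are derived deterministically from a single master seed by
hashing (master_seed, algorithm, k), so a full experiment is reproducible
bit-for-bit from its configuration alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .feature_selection import (
    EaConfig,
    SelectionResult,
    aco_select,
    ga_select,
    nsga2_select,
    pso_select,
    sa_select,
    stat_select,
)
from .graph_features import FEATURE_SEP, FeatureTable

__all__ = [
    "AccuracyCurve",
    "PresenceProfile",
    "derive_seed",
    "run_selector",
    "accuracy_vs_k",
    "moving_average",
    "baseline_superiority",
    "feature_presence",
    "top_feature_report",
]

ALGORITHMS = ("ga", "nsga2", "aco", "sa", "pso", "stat")


def derive_seed(master_seed: int, algorithm: str, k: int) -> int:
    """Deterministic per-cell seed from (master_seed, algorithm, k)."""
    digest = hashlib.sha256(f"{master_seed}:{algorithm}:{k}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


def run_selector(
    algorithm: str, table: FeatureTable, k: int, cfg: EaConfig
) -> SelectionResult:
    """Dispatch one fixed-k search.  NSGA-II is run with k_max=k and the
    best archived subset of cardinality <= k is reported at that k."""
    if algorithm == "ga":
        return ga_select(table, k, cfg)
    if algorithm == "sa":
        return sa_select(table, k, cfg)
    if algorithm == "pso":
        return pso_select(table, k, cfg)
    if algorithm == "aco":
        return aco_select(table, k, cfg)
    if algorithm == "stat":
        return stat_select(table, k, cfg)
    if algorithm == "nsga2":
        res = nsga2_select(table, k, cfg)
        best = max(res.per_k.values(), key=lambda r: r.best_fitness)
        return best
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class AccuracyCurve:
    """Best accuracy (%) per subset cardinality for one algorithm."""

    ks: list[int]
    accuracies: list[float]
    algorithm: str
    master_seed: int

    def __post_init__(self) -> None:
        if list(self.ks) != sorted(set(self.ks)):
            raise ValueError("ks must be strictly increasing")
        if any(not (0 <= a <= 100) for a in self.accuracies):
            raise ValueError("accuracies must lie in [0, 100]")


def accuracy_vs_k(
    table: FeatureTable,
    algorithm: str,
    k_range: Iterable[int],
    cfg: EaConfig,
    master_seed: int = 0,
) -> tuple[AccuracyCurve, list[SelectionResult]]:
    """One search per cardinality k, each with its derived seed."""
    ks = sorted(set(int(k) for k in k_range))
    results: list[SelectionResult] = []
    for k in ks:
        cell_cfg = replace(cfg, seed=derive_seed(master_seed, algorithm, k))
        results.append(run_selector(algorithm, table, k, cell_cfg))
    curve = AccuracyCurve(
        ks=ks,
        accuracies=[r.best_fitness for r in results],
        algorithm=algorithm,
        master_seed=master_seed,
    )
    return curve, results


def moving_average(values: Sequence[float], halfwidth: int = 20) -> np.ndarray:
    """Mean over a +/-halfwidth window, shrinking at the edges.

    Point i averages the points with indices in [i-halfwidth, i+halfwidth]
    clipped to the series, so endpoints remain local and no padding is
    introduced.  halfwidth=0 is the identity.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for i in range(v.size):
        lo = max(0, i - halfwidth)
        hi = min(v.size, i + halfwidth + 1)
        out[i] = v[lo:hi].mean()
    return out


def baseline_superiority(
    ea_curve: AccuracyCurve, stat_curve: AccuracyCurve
) -> tuple[np.ndarray, float]:
    """Per-k accuracy difference (search minus baseline) and its mean."""
    if list(ea_curve.ks) != list(stat_curve.ks):
        raise ValueError("curves must share an identical k grid")
    diff = np.asarray(ea_curve.accuracies) - np.asarray(stat_curve.accuracies)
    return diff, float(diff.mean())


@dataclass
class PresenceProfile:
    """How often each feature appears across a sequence of search results."""

    counts: np.ndarray  # per-feature selection count
    cumulative_unique: list[int]  # unique features seen up to each result
    n_results: int


def feature_presence(results: Sequence[SelectionResult], n_features: int | None = None) -> PresenceProfile:
    """Selection counts per feature and cumulative unique-feature counts.

    Results are consumed in the order given (typically increasing k).
    """
    if not results:
        raise ValueError("need at least one result")
    if n_features is None:
        n_features = max(max(r.best_indices) for r in results) + 1
    counts = np.zeros(n_features, dtype=int)
    seen: set[int] = set()
    cumulative: list[int] = []
    for r in results:
        for i in r.best_indices:
            counts[i] += 1
        seen.update(r.best_indices)
        cumulative.append(len(seen))
    return PresenceProfile(counts=counts, cumulative_unique=cumulative, n_results=len(results))


def top_feature_report(
    profile: PresenceProfile, feature_names: Sequence[str], top_n: int = 5
) -> list[dict]:
    """The top_n most frequently selected features, ties by lower index.

    Feature names of the form "<node>::<measure>" are split back into their
    node and measure parts.
    """
    if top_n > len(feature_names):
        raise ValueError("top_n exceeds the number of features")
    order = np.lexsort((np.arange(profile.counts.size), -profile.counts))
    report = []
    for i in order[:top_n]:
        name = feature_names[i]
        node, _, measure = name.partition(FEATURE_SEP)
        report.append(
            {
                "feature_index": int(i),
                "feature_name": name,
                "node": node,
                "measure": measure or name,
                "count": int(profile.counts[i]),
            }
        )
    return report
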