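"""Synthetic two-group cohorts with known ground truth.

Real resting-state cohorts of the kind this package targets are access
controlled, so every pipeline stage is exercised on generated data instead.
Two levels are supported:

* feature level — a subjects x features table of Gaussian noise in which a
  known subset of columns carries a mean shift (a standardized effect)
  between the groups; this stands in for an extracted graph-measure table
  and gives the subset searches a planted answer to find.

* time-series level — per-subject multivariate Gaussian ROI time series
  whose covariance contains a designated ROI block with within-block
  correlation rho0 in group 0 and rho0 + delta_rho in group 1, so the
  group difference only appears after the full connectivity -> graph ->
  measure chain.

Defaults mirror the emulated study conditions: 72 + 68 subjects, 140
timepoints at a 3.0 s sampling interval.  Everything is deterministic
given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectivity import RoiTimeSeries
from .graph_features import FeatureTable

__all__ = ["CohortSpec", "GroundTruth", "generate_feature_cohort", "generate_timeseries_cohort"]


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect`` is the standardized mean difference per informative feature
    (feature level) or the within-block correlation contrast delta_rho
    (time-series level, added to ``rho0`` in group 1).
    """

    n_group0: int = 72
    n_group1: int = 68
    level: str = "feature"  # "feature" | "timeseries"
    n_features: int = 200
    n_informative: int = 10
    effect: float = 1.0
    noise_sd: float = 1.0
    # time-series level
    n_roi: int = 16
    n_timepoints: int = 140
    dt: float = 3.0
    rho0: float = 0.2
    block_size: int = 4
    seed: int = 0
    group_names: tuple[str, str] = ("HC", "EMCI")

    def __post_init__(self) -> None:
        if self.n_group0 < 2 or self.n_group1 < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.level not in ("feature", "timeseries"):
            raise ValueError("level must be 'feature' or 'timeseries'")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.level == "feature" and self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.level == "timeseries" and self.block_size > self.n_roi:
            raise ValueError("block_size cannot exceed n_roi")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    informative_indices: tuple[int, ...]
    effect: float
    seed: int
    block_labels: tuple[str, ...] = ()
    block_edges: tuple[tuple[str, str], ...] = ()
    rho: tuple[float, float] = (0.0, 0.0)  # (group0, group1) within-block correlation


def generate_feature_cohort(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Feature-level cohort: Gaussian noise + planted mean-shifted columns.

    All columns are Normal(0, noise_sd) in both groups; in group 1 the
    informative columns are shifted by effect * noise_sd, i.e. ``effect``
    is the standardized mean difference.
    """
    if spec.level != "feature":
        raise ValueError("spec.level must be 'feature'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_group0 + spec.n_group1
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    informative = np.sort(rng.choice(spec.n_features, size=spec.n_informative, replace=False))
    labels = np.concatenate([np.zeros(spec.n_group0, int), np.ones(spec.n_group1, int)])
    if spec.n_informative:
        X[np.ix_(labels == 1, informative)] += spec.effect * spec.noise_sd
    names = [f"f{i:04d}" for i in range(spec.n_features)]
    table = FeatureTable(
        data=X,
        feature_names=names,
        labels=labels,
        group_names=spec.group_names,
    )
    truth = GroundTruth(
        informative_indices=tuple(int(i) for i in informative),
        effect=spec.effect,
        seed=spec.seed,
    )
    return table, truth


def _block_covariance(n_roi: int, block: Sequence[int], rho: float) -> np.ndarray:
    """Unit-variance covariance with an equicorrelated block; checks PD."""
    b = len(block)
    if not (-1.0 / max(b - 1, 1) < rho < 1.0):
        raise ValueError(f"within-block correlation {rho} is not positive definite for block size {b}")
    cov = np.eye(n_roi)
    for i in block:
        for j in block:
            if i != j:
                cov[i, j] = rho
    return cov


def generate_timeseries_cohort(
    spec: CohortSpec,
) -> tuple[list[RoiTimeSeries], np.ndarray, GroundTruth]:
    """Time-series cohort with a group-dependent correlated ROI block.

    Each subject is an independent T x n_roi draw from a zero-mean Gaussian
    whose covariance is the identity except for an equicorrelated block of
    ``block_size`` ROIs: correlation rho0 in group 0 and rho0 + effect in
    group 1.  Raises before sampling if either covariance is not positive
    definite.
    """
    if spec.level != "timeseries":
        raise ValueError("spec.level must be 'timeseries'")
    rng = np.random.default_rng(spec.seed)
    block = list(range(spec.block_size))
    rho1 = spec.rho0 + spec.effect
    chol = {}
    for g, rho in ((0, spec.rho0), (1, rho1)):
        cov = _block_covariance(spec.n_roi, block, rho)
        chol[g] = np.linalg.cholesky(cov)

    roi_labels = [f"ROI_{i:03d}" for i in range(1, spec.n_roi + 1)]
    labels = np.concatenate([np.zeros(spec.n_group0, int), np.ones(spec.n_group1, int)])
    cohort: list[RoiTimeSeries] = []
    for s, g in enumerate(labels):
        z = rng.standard_normal((spec.n_timepoints, spec.n_roi))
        data = spec.noise_sd * (z @ chol[g].T)
        cohort.append(
            RoiTimeSeries(f"sub-{s + 1:03d}", data, roi_labels, dt=spec.dt)
        )
    block_labels = tuple(roi_labels[i] for i in block)
    edges = tuple(
        (block_labels[i], block_labels[j])
        for i in range(len(block_labels))
        for j in range(i + 1, len(block_labels))
    )
    truth = GroundTruth(
        informative_indices=tuple(block),
        effect=spec.effect,
        seed=spec.seed,
        block_labels=block_labels,
        block_edges=edges,
        rho=(spec.rho0, rho1),
    )
    return cohort, labels, truth
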