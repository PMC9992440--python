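"""Trajectory summary metrics, two-group partitioning and A/B sub-origin labels.

Each backtrack simulation is reduced to two metrics — the mean distance
travelled per particle and the mean latitude of the particle origins, each
with a 95% confidence interval over the 100-particle ensemble — and the
simulations are partitioned by K-means (k = 2, z-scored features).  The
cluster with the greater mean travel distance is labelled pathway A (the
long meandering equatorial route); consistency with the expectation that A
also has the lower origin latitude is checked, and a disagreement is
resolved in favour of distance with a recorded warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .tracker import BacktrackResult

__all__ = ["TrackMetrics", "SubOriginAssignment", "compute_track_metrics", "partition_kmeans", "label_suborigins"]

Z95 = 1.96


@dataclass(frozen=True)
class TrackMetrics:
    """Per-simulation ensemble summaries (means over the particle ensemble)."""

    simulation_id: str
    mean_distance_km: float
    distance_ci95: tuple
    mean_origin_lat: float
    lat_ci95: tuple
    mean_origin_lon: float

    def __post_init__(self) -> None:
        if not (self.distance_ci95[0] <= self.mean_distance_km <= self.distance_ci95[1]):
            raise ValueError("distance CI must bracket the mean")
        if not (self.lat_ci95[0] <= self.mean_origin_lat <= self.lat_ci95[1]):
            raise ValueError("latitude CI must bracket the mean")


@dataclass
class SubOriginAssignment:
    """Cluster index and A/B label per simulation, with clustering diagnostics."""

    cluster_of: dict  # simulation_id -> cluster index
    centers: np.ndarray  # cluster centers in z-scored (distance, latitude) space
    inertia: float
    labels: dict = field(default_factory=dict)  # simulation_id -> 'A' / 'B'
    label_of_cluster: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _mean_ci(x: np.ndarray):
    n = len(x)
    m = float(np.mean(x))
    half = Z95 * float(np.std(x, ddof=1)) / np.sqrt(n)
    return m, (m - half, m + half)


def compute_track_metrics(result: BacktrackResult) -> TrackMetrics:
    """Mean and 95% CI (mean +- 1.96 sd/sqrt(n)) of distance and origin latitude."""
    n = result.positions.shape[1]
    if n < 2:
        raise ValueError("confidence intervals require at least two particles")
    dist_mean, dist_ci = _mean_ci(result.cumdist_km[-1])
    lat_mean, lat_ci = _mean_ci(result.endpoints[:, 1])
    return TrackMetrics(
        simulation_id=result.simulation_id,
        mean_distance_km=dist_mean,
        distance_ci95=dist_ci,
        mean_origin_lat=lat_mean,
        lat_ci95=lat_ci,
        mean_origin_lon=float(result.endpoints[:, 0].mean()),
    )


def metrics_to_dataframe(metrics) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "simulation": [m.simulation_id for m in metrics],
            "mean_distance_km": [m.mean_distance_km for m in metrics],
            "distance_ci_lo": [m.distance_ci95[0] for m in metrics],
            "distance_ci_hi": [m.distance_ci95[1] for m in metrics],
            "mean_origin_lat": [m.mean_origin_lat for m in metrics],
            "lat_ci_lo": [m.lat_ci95[0] for m in metrics],
            "lat_ci_hi": [m.lat_ci95[1] for m in metrics],
            "mean_origin_lon": [m.mean_origin_lon for m in metrics],
        }
    )


def partition_kmeans(metrics, k: int = 2, seed: int = 0) -> SubOriginAssignment:
    """K-means on z-scored (mean distance, mean origin latitude); best of 10 restarts."""
    metrics = list(metrics)
    if len(metrics) < k:
        raise ValueError(f"need at least k={k} simulations")
    x = np.array([[m.mean_distance_km, m.mean_origin_lat] for m in metrics])
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0) and np.all(x.std(axis=0) == 0):
        raise ValueError("degenerate metrics: all simulations identical")
    z = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
    if len(np.unique(km.labels_)) < k:
        raise ValueError("K-means produced an empty cluster (degenerate metrics)")
    return SubOriginAssignment(
        cluster_of={m.simulation_id: int(c) for m, c in zip(metrics, km.labels_)},
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def label_suborigins(assignment: SubOriginAssignment, metrics) -> SubOriginAssignment:
    """Label the longer-distance cluster 'A', the other 'B' (two clusters).

    Pathway A is the equatorial meandering route, so its cluster should also
    have the lower mean origin latitude; if distance and latitude disagree,
    distance wins and a warning is recorded.
    """
    by_sim = {m.simulation_id: m for m in metrics}
    clusters = sorted(set(assignment.cluster_of.values()))
    if len(clusters) != 2:
        raise ValueError("labelling requires exactly two clusters")
    mean_dist = {}
    mean_lat = {}
    for c in clusters:
        ms = [by_sim[s] for s, ci in assignment.cluster_of.items() if ci == c]
        mean_dist[c] = float(np.mean([m.mean_distance_km for m in ms]))
        mean_lat[c] = float(np.mean([m.mean_origin_lat for m in ms]))
    a_by_dist = max(clusters, key=lambda c: mean_dist[c])
    a_by_lat = min(clusters, key=lambda c: mean_lat[c])
    if a_by_dist != a_by_lat:
        msg = (
            "distance and origin-latitude criteria disagree on which cluster is "
            "pathway A; labelling by distance"
        )
        warnings.warn(msg)
        assignment.warnings.append(msg)
    assignment.label_of_cluster = {c: ("A" if c == a_by_dist else "B") for c in clusters}
    assignment.labels = {s: assignment.label_of_cluster[c] for s, c in assignment.cluster_of.items()}
    return assignment
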