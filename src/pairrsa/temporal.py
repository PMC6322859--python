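"""Temporal-pattern similarity maps and the sensor cluster permutation test.

Within the analysis window established by the spatial similarity stage,
the time course at each sensor is correlated (Pearson, over time samples)
between the two members of every comparison, yielding one topographic map
of R values per comparison. Condition averages (within vs between) are
compared with a cluster-based permutation test whose clusters are formed
in a sensor neighborhood graph (default: sensors within 40 mm):

* statistic per sensor: group-mean within-minus-between difference,
* cluster-forming threshold: the 95th percentile of that difference
  across sensors — recomputed inside every permutation so the observed
  statistic and the null are computed identically,
* cluster mass: sum of mean differences over the connected component,
* null: per-participant condition swaps (sign flips), max mass per
  permutation, two tails at 2.5% each.

Because a percentile threshold always admits some sensors, inference
rests entirely on the max-mass null, never on the mere existence of a
supra-threshold cluster.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import (
    Cluster,
    ClusterResult,
    EpochSet,
    SensorNeighborGraph,
    TopographicMap,
    window_mask,
)
from .design import ComparisonSet
from .stats import PermutationPlan, perm_p_value, percentile, sign_flips

__all__ = [
    "temporal_similarity_map",
    "average_condition_maps",
    "sensor_cluster_test",
    "map_cluster_test",
]


def _znorm_temporal(data: np.ndarray) -> np.ndarray:
    """Center/unit-norm each (trial, sensor) time course; constant series
    become NaN rows (undefined correlation)."""
    z = data - data.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(z, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = z / norm
    z[np.broadcast_to(norm == 0, z.shape)] = np.nan
    return z


def temporal_similarity_map(
    trial_a: np.ndarray,
    trial_b: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    sensor_ids: list[str] | None = None,
    label: str = "",
) -> TopographicMap:
    """Per-sensor Pearson correlation of two trials' time courses inside
    ``window`` (at least 3 samples)."""
    trial_a = np.asarray(trial_a, dtype=float)
    trial_b = np.asarray(trial_b, dtype=float)
    if trial_a.shape != trial_b.shape:
        raise ValueError("trials must share sensor and time axes")
    idx = np.flatnonzero(window_mask(np.asarray(times, dtype=float), window))
    if idx.size < 3:
        raise ValueError("window must contain at least 3 samples")
    za = _znorm_temporal(trial_a[:, idx])
    zb = _znorm_temporal(trial_b[:, idx])
    r = np.clip(np.sum(za * zb, axis=-1), -1.0, 1.0)
    ids = sensor_ids or [f"S{i:03d}" for i in range(trial_a.shape[0])]
    return TopographicMap(r_per_sensor=r, sensor_ids=ids, label=label, window=window)


def condition_map_per_participant(
    epochs: EpochSet, cset: ComparisonSet, window: tuple[float, float]
) -> tuple[np.ndarray, int]:
    """Comparison-averaged temporal-similarity map for one participant.

    NaN (undefined) comparisons are excluded per sensor.
    """
    idx = np.flatnonzero(window_mask(epochs.times, window))
    if idx.size < 3:
        raise ValueError("window must contain at least 3 samples")
    index = epochs.trial_index()
    pairs = [(index[a], index[b]) for a, b in cset if a in index and b in index]
    if not pairs:
        raise ValueError(f"no available comparisons for condition {cset.label!r}")
    z = _znorm_temporal(epochs.data[..., idx])
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    # Gram over trials per sensor: (S, n, Tw) @ (S, Tw, n) -> (S, n, n)
    zs = np.ascontiguousarray(z.transpose(1, 0, 2))
    gram = zs @ zs.swapaxes(1, 2)
    r = gram[:, ia, ib]  # (S, n_comparisons)
    good = np.isfinite(r)
    acc = np.where(good, r, 0.0).sum(axis=1)
    cnt = good.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    return np.clip(mean, -1.0, 1.0), len(pairs)


def average_condition_maps(
    epoch_sets: list[EpochSet], cset: ComparisonSet, window: tuple[float, float]
) -> tuple[np.ndarray, TopographicMap]:
    """Per-participant maps (n_participants, n_sensors) and the group mean."""
    maps = np.empty((len(epoch_sets), epoch_sets[0].n_sensors))
    n_used = 0
    for i, es in enumerate(epoch_sets):
        maps[i], n = condition_map_per_participant(es, cset, window)
        n_used += n
    group = TopographicMap(
        r_per_sensor=np.nanmean(maps, axis=0),
        sensor_ids=list(epoch_sets[0].sensor_ids),
        label=f"{cset.label}_group",
        window=window,
        n_comparisons=n_used,
    )
    return maps, group


def _components(adjacency: np.ndarray, supra: np.ndarray) -> list[np.ndarray]:
    """Connected components of the supra-threshold node subset."""
    nodes = np.flatnonzero(supra)
    if nodes.size == 0:
        return []
    sub = adjacency[np.ix_(nodes, nodes)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    return [nodes[labels == k] for k in range(n_comp)]


def _extreme_masses(
    diff_mean: np.ndarray, adjacency: np.ndarray, q: float
) -> tuple[float, float, float, float]:
    """(max positive mass, min negative mass, upper threshold, lower
    threshold) for one (permuted) group-mean difference map."""
    finite = np.isfinite(diff_mean)
    vals = diff_mean[finite]
    hi = percentile(vals, q)
    lo = percentile(vals, 100.0 - q)
    pos = _components(adjacency, finite & (diff_mean > hi))
    neg = _components(adjacency, finite & (diff_mean < lo))
    max_mass = max((float(diff_mean[c].sum()) for c in pos), default=0.0)
    min_mass = min((float(diff_mean[c].sum()) for c in neg), default=0.0)
    return max_mass, min_mass, hi, lo


def map_cluster_test(
    within_maps: np.ndarray,
    between_maps: np.ndarray,
    adjacency: np.ndarray,
    plan: PermutationPlan = PermutationPlan(),
    percentile_q: float = 95.0,
) -> ClusterResult:
    """Generic percentile-threshold cluster-mass permutation test on
    per-participant value maps over any neighborhood structure (sensors or
    source grid points)."""
    within_maps = np.asarray(within_maps, dtype=float)
    between_maps = np.asarray(between_maps, dtype=float)
    if within_maps.shape != between_maps.shape or within_maps.ndim != 2:
        raise ValueError("expect (n_participants, n_nodes) map stacks")
    n, s = within_maps.shape
    if n < 2:
        raise ValueError("need >= 2 participants")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (s, s):
        raise ValueError("adjacency does not match map size")
    diffs = within_maps - between_maps

    diff_mean = np.nanmean(diffs, axis=0)
    finite = np.isfinite(diff_mean)
    if not finite.any():
        raise ValueError("all node differences undefined")
    hi = percentile(diff_mean[finite], percentile_q)
    lo = percentile(diff_mean[finite], 100.0 - percentile_q)
    observed: list[tuple[np.ndarray, float, str]] = []
    for c in _components(adjacency, finite & (diff_mean > hi)):
        observed.append((c, float(diff_mean[c].sum()), "positive"))
    for c in _components(adjacency, finite & (diff_mean < lo)):
        observed.append((c, float(diff_mean[c].sum()), "negative"))

    flips = sign_flips(plan, n)
    null_max = np.zeros(plan.n_perm)
    null_min = np.zeros(plan.n_perm)
    for k in range(plan.n_perm):
        m = np.nanmean(diffs * flips[k][:, None], axis=0)
        null_max[k], null_min[k], _, _ = _extreme_masses(m, adjacency, percentile_q)

    clusters = []
    for members, mass, tail in observed:
        if tail == "positive":
            p = perm_p_value(null_max, mass)
        else:
            p = perm_p_value(-null_min, -mass)
        clusters.append(Cluster(members=members, mass=mass, tail=tail, p_value=p))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=clusters,
        null_max=null_max,
        null_min=null_min,
        n_perm=plan.n_perm,
        threshold=(hi, lo),
        shape=(s,),
    )


def sensor_cluster_test(
    within_maps: np.ndarray,
    between_maps: np.ndarray,
    graph: SensorNeighborGraph,
    plan: PermutationPlan = PermutationPlan(),
    percentile_q: float = 95.0,
) -> ClusterResult:
    """Sensor-level cluster permutation test (see module docstring)."""
    if graph.n_nodes == 0:
        raise ValueError("empty sensor graph")
    return map_cluster_test(
        within_maps, between_maps, graph.adjacency, plan=plan,
        percentile_q=percentile_q,
    )
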