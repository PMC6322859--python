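"""Spatial-pattern similarity analyses.

The central quantity is the instantaneous spatial correlation: at each
time sample, the sensor-pattern vectors of two trials are correlated
(Pearson, across sensors). Averaging those correlation time series over
the within-pair comparisons (N for N pairs) and over the between-pair
comparisons (2N(N-1)) — raw R values, no Fisher transform — gives the two
condition time series whose window-averaged difference is tested with a
paired t-test over participants.

The cross-temporal (temporal-generalization) variant correlates the
pattern of one pair member at time i with the other member's pattern at
time j for all (i, j), after resampling to 300 Hz; the resulting
correlation surface is smoothed with a Gaussian kernel along both time
axes. Within-vs-between differences of these matrices are tested with a
cluster-mass permutation test over time x time cells (per-cell paired t,
4-neighbor connectivity, max-mass null from per-participant sign flips).

Samples where a pattern has zero across-sensor variance yield an
undefined correlation; these are carried as NaN and excluded from
averages, never imputed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats as sp_stats

from .containers import (
    Cluster,
    TrialInfo,
    ClusterResult,
    CrossTemporalMatrix,
    EpochSet,
    SimilarityTimeSeries,
    WindowResult,
    window_mask,
)
from .design import ComparisonSet, PairDesign, split_by_order
from .preprocess import SmoothSpec, gaussian_smooth, resample
from .stats import PermutationPlan, paired_t, perm_p_value, rm_anova_2x2, sign_flips

__all__ = [
    "spatial_similarity_series",
    "average_condition_series",
    "condition_window_means",
    "detect_window",
    "window_test",
    "order_anova",
    "cross_temporal_matrix",
    "average_condition_matrices",
    "matrix_cluster_test",
]


def _znorm_spatial(data: np.ndarray) -> np.ndarray:
    """Center and unit-norm each (trial, time) sensor vector.

    With this normalization the Pearson correlation between two patterns
    is the plain dot product of their normalized vectors. Zero-variance
    vectors become NaN columns (undefined correlation).
    """
    z = data - data.mean(axis=-2, keepdims=True)
    norm = np.linalg.norm(z, axis=-2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = z / norm
    z[np.broadcast_to(norm == 0, z.shape)] = np.nan
    return z


def spatial_similarity_series(
    trial_a: np.ndarray,
    trial_b: np.ndarray,
    times: np.ndarray,
    label: str = "",
) -> SimilarityTimeSeries:
    """Pearson correlation across sensors at every time sample.

    ``trial_a`` and ``trial_b`` are (n_sensors, n_times) on identical
    sensor sets and time axes.
    """
    trial_a = np.asarray(trial_a, dtype=float)
    trial_b = np.asarray(trial_b, dtype=float)
    times = np.asarray(times, dtype=float)
    if trial_a.shape != trial_b.shape:
        raise ValueError("trials must share sensor and time axes")
    if trial_a.shape[1] != times.size:
        raise ValueError("time axis does not match data")
    za = _znorm_spatial(trial_a)
    zb = _znorm_spatial(trial_b)
    r = np.sum(za * zb, axis=0)
    r = np.clip(r, -1.0, 1.0)
    return SimilarityTimeSeries(r=r, times=times, label=label, n_comparisons=1)


def _mean_r_over_comparisons(
    epochs: EpochSet,
    cset: ComparisonSet,
    time_idx: np.ndarray,
    fisher_z: bool = False,
) -> tuple[np.ndarray, int]:
    """Mean spatial correlation over a comparison set for one participant.

    Comparisons whose trials are missing are dropped (count returned);
    undefined samples (NaN) are excluded per sample. With ``fisher_z`` the
    per-comparison r values are arctanh-transformed before averaging and
    the mean is transformed back (off by default: raw R values are
    averaged). Returns (mean r over selected samples, n comparisons used).
    """
    index = epochs.trial_index()
    pairs = [(index[a], index[b]) for a, b in cset if a in index and b in index]
    if not pairs:
        raise ValueError(f"no available comparisons for condition {cset.label!r}")
    z = _znorm_spatial(epochs.data[..., time_idx])
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    # all pairwise dot products per time sample via batched matmul:
    # (T, n_trials, S) @ (T, S, n_trials) -> Gram (T, n_trials, n_trials)
    zt = np.ascontiguousarray(z.transpose(2, 0, 1))
    gram = zt @ zt.swapaxes(1, 2)
    r = gram[:, ia, ib]  # (T, n_comparisons)
    if fisher_z:
        with np.errstate(divide="ignore"):
            r = np.arctanh(np.clip(r, -1.0, 1.0))
    good = np.isfinite(r)
    acc = np.where(good, r, 0.0).sum(axis=1)
    cnt = good.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    if fisher_z:
        mean = np.tanh(mean)
    return np.clip(mean, -1.0, 1.0), len(pairs)


def average_condition_series(
    epoch_sets: list[EpochSet], cset: ComparisonSet, fisher_z: bool = False
) -> tuple[list[SimilarityTimeSeries], SimilarityTimeSeries]:
    """Condition-averaged similarity series per participant, then the
    group mean (arithmetic means of raw R values; ``fisher_z`` switches to
    averaging arctanh-transformed values, back-transformed)."""
    times = epoch_sets[0].times
    per_participant = []
    for es in epoch_sets:
        mean, n_used = _mean_r_over_comparisons(es, cset, np.arange(es.n_times),
                                                fisher_z=fisher_z)
        per_participant.append(
            SimilarityTimeSeries(r=mean, times=times, label=cset.label,
                                 n_comparisons=n_used)
        )
    stack = np.array([s.r for s in per_participant])
    group = SimilarityTimeSeries(
        r=np.nanmean(stack, axis=0),
        times=times,
        label=f"{cset.label}_group",
        n_comparisons=sum(s.n_comparisons for s in per_participant),
    )
    return per_participant, group


def condition_window_means(
    epoch_sets: list[EpochSet], cset: ComparisonSet, interval: tuple[float, float]
) -> np.ndarray:
    """Per-participant mean R over a time window (one value per
    participant), computing correlations only inside the window."""
    out = np.empty(len(epoch_sets))
    for i, es in enumerate(epoch_sets):
        idx = np.flatnonzero(window_mask(es.times, interval))
        if idx.size == 0:
            raise ValueError("interval contains no samples")
        mean, _ = _mean_r_over_comparisons(es, cset, idx)
        out[i] = np.nanmean(mean)
    return out


def detect_window(
    combined: SimilarityTimeSeries,
    threshold: float = 0.04,
    search_interval: tuple[float, float] | None = None,
) -> tuple[float, float] | None:
    """Longest contiguous supra-threshold run of the combined series.

    ``combined`` is the mean of the within- and between-condition group
    averages. Returns the first/last sample times of the longest run with
    r > threshold inside ``search_interval``, or None when no sample
    exceeds the threshold.
    """
    r = combined.r
    times = combined.times
    mask = np.isfinite(r) & (r > threshold)
    if search_interval is not None:
        mask &= window_mask(times, search_interval)
    if not mask.any():
        return None
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    best = np.argmax(ends - starts)
    return float(times[starts[best]]), float(times[ends[best] - 1])


def window_test(
    within_means: np.ndarray,
    between_means: np.ndarray,
    interval: tuple[float, float],
) -> WindowResult:
    """Two-sided paired t-test on window-averaged within vs between R."""
    within_means = np.asarray(within_means, dtype=float)
    between_means = np.asarray(between_means, dtype=float)
    if within_means.size < 2:
        raise ValueError("need >= 2 participants")
    t, df, p, degenerate = paired_t(within_means, between_means)
    return WindowResult(
        interval=interval,
        mean_r_within=float(within_means.mean()),
        mean_r_between=float(between_means.mean()),
        t_statistic=t,
        df=df,
        p_value=p,
        degenerate=degenerate,
    )


def order_anova(
    epoch_sets: list[EpochSet],
    design: PairDesign,
    interval: tuple[float, float],
) -> dict[str, dict[str, float]]:
    """2 x 2 repeated-measures ANOVA: Order (expected-SFW first vs
    unexpected-SFW first) x Pairs (within vs between) on window-averaged
    R values. Returns F, df, p and partial eta squared per effect under
    keys "Order", "Pairs", "OrderxPairs"."""
    groups = split_by_order(design)
    cells = np.empty((len(epoch_sets), 2, 2))
    for oi, okey in enumerate(("expected_first", "unexpected_first")):
        for ci, ckey in enumerate(("within", "between")):
            cset = groups[okey][ckey]
            if len(cset) == 0:
                raise ValueError(f"empty cell {okey}/{ckey}")
            cells[:, oi, ci] = condition_window_means(epoch_sets, cset, interval)
    res = rm_anova_2x2(cells)
    return {"Order": res["A"], "Pairs": res["B"], "OrderxPairs": res["AxB"]}


def _resample_epochs(epochs: EpochSet, target_rate: float) -> EpochSet:
    if abs(epochs.sample_rate - target_rate) <= 1e-9 * target_rate:
        return epochs
    return resample(epochs, target_rate)


def cross_temporal_matrix(
    trial_a: np.ndarray,
    trial_b: np.ndarray,
    times: np.ndarray,
    sample_rate: float,
    target_rate: float = 300.0,
    smooth: SmoothSpec | None = SmoothSpec(),
    interval: tuple[float, float] | None = None,
    label: str = "",
) -> CrossTemporalMatrix:
    """Correlation of trial A's pattern at time i with trial B's at time j.

    Data are resampled to ``target_rate``, optionally restricted to
    ``interval``; the correlation surface is smoothed along both time axes
    (``smooth=None`` disables smoothing, leaving the raw surface whose
    diagonal equals the similarity time series on the resampled axis).
    """
    trial_a = np.asarray(trial_a, dtype=float)
    trial_b = np.asarray(trial_b, dtype=float)
    if trial_a.shape != trial_b.shape:
        raise ValueError("trials must share sensor and time axes")
    es = EpochSet(
        data=np.stack([trial_a, trial_b]),
        times=times,
        sensor_ids=[f"S{i}" for i in range(trial_a.shape[0])],
        trials=[
            TrialInfo(0, 0, 1, "expected", "noun"),
            TrialInfo(1, 0, 2, "unexpected", "noun"),
        ],
    )
    es = _resample_epochs(es, target_rate)
    t = es.times
    if interval is not None:
        idx = np.flatnonzero(window_mask(t, interval))
        t = t[idx]
    else:
        idx = np.arange(t.size)
    za = _znorm_spatial(es.data[0][:, idx])
    zb = _znorm_spatial(es.data[1][:, idx])
    m = za.T @ zb
    m = np.clip(m, -1.0, 1.0)
    if smooth is not None:
        m = gaussian_smooth(m, smooth, target_rate, axis=0)
        m = gaussian_smooth(m, smooth, target_rate, axis=1)
    return CrossTemporalMatrix(r=m, times_row=t, times_col=t, label=label)


def average_condition_matrices(
    epoch_sets: list[EpochSet],
    cset: ComparisonSet,
    interval: tuple[float, float],
    target_rate: float = 300.0,
    smooth: SmoothSpec | None = SmoothSpec(),
) -> np.ndarray:
    """Per-participant condition-averaged cross-temporal matrices.

    Returns an array (n_participants, n_t, n_t). Smoothing is applied to
    the per-participant average (equivalent to smoothing each comparison's
    surface, by linearity).
    """
    out = None
    for pi, es in enumerate(epoch_sets):
        res = _resample_epochs(es, target_rate)
        idx = np.flatnonzero(window_mask(res.times, interval))
        if idx.size < 2:
            raise ValueError("interval contains < 2 samples after resampling")
        z = _znorm_spatial(res.data[..., idx])
        index = es.trial_index()
        pairs = [(index[a], index[b]) for a, b in cset if a in index and b in index]
        if not pairs:
            raise ValueError(f"no available comparisons for {cset.label!r}")
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        # batched matmul over comparisons: (n, T, S) @ (n, S, T) -> (n, T, T)
        a = z[ia].transpose(0, 2, 1)
        b = z[ib]
        mats = a @ b
        avg = np.nanmean(mats, axis=0)
        avg = np.clip(avg, -1.0, 1.0)
        if smooth is not None:
            avg = gaussian_smooth(avg, smooth, target_rate, axis=0)
            avg = gaussian_smooth(avg, smooth, target_rate, axis=1)
        if out is None:
            out = np.empty((len(epoch_sets), idx.size, idx.size))
        out[pi] = avg
    return out


def _t_matrix(diffs: np.ndarray) -> np.ndarray:
    """Per-cell paired t over the participant axis of (P, ...) differences."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _max_mass(t: np.ndarray, mask: np.ndarray) -> float:
    """Largest summed-t mass over connected components of ``mask`` (0 if
    none); mass-only fast path for the permutation null."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0.0
    return float(np.max(ndimage.sum_labels(t, labels, index=np.arange(1, n + 1))))


def _matrix_clusters(t: np.ndarray, t_crit: float) -> list[tuple[np.ndarray, float, str]]:
    """4-connected supra-threshold clusters of a t matrix, both tails."""
    out = []
    for tail, mask in (("positive", t >= t_crit), ("negative", t <= -t_crit)):
        labels, n = ndimage.label(mask)  # default structure = 4-connectivity
        for k in range(1, n + 1):
            members = np.flatnonzero(labels.ravel() == k)
            mass = float(t.ravel()[members].sum())
            out.append((members, mass, tail))
    return out


def matrix_cluster_test(
    within_mats: np.ndarray,
    between_mats: np.ndarray,
    plan: PermutationPlan = PermutationPlan(),
    alpha_cell: float = 0.05,
) -> ClusterResult:
    """Cluster-mass permutation test on cross-temporal matrix differences.

    Per-cell paired t-tests over participants; cells with uncorrected
    p <= ``alpha_cell`` form 4-connected clusters whose summed t values
    give the cluster mass. The null re-assigns condition labels within
    each participant (sign flips of the difference matrices) and records
    the extreme mass per permutation; clusters in the highest or lowest
    2.5% of the null are significant (p convention (b+1)/(n_perm+1)).
    """
    within_mats = np.asarray(within_mats, dtype=float)
    between_mats = np.asarray(between_mats, dtype=float)
    if within_mats.shape != between_mats.shape or within_mats.ndim != 3:
        raise ValueError("expect (n_participants, T, T) matrix stacks")
    n = within_mats.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    diffs = within_mats - between_mats
    t_crit = float(sp_stats.t.ppf(1.0 - alpha_cell / 2.0, n - 1))

    observed = _matrix_clusters(_t_matrix(diffs), t_crit)
    flips = sign_flips(plan, n)
    null_max = np.zeros(plan.n_perm)
    null_min = np.zeros(plan.n_perm)
    # The per-cell sum of squares is invariant under sign flips, so every
    # permuted t matrix follows from one (n_perm, n) x (n, cells) matmul,
    # and |t| >= t_crit reduces to a closed-form bound on the flipped mean:
    #   t^2 = n(n-1) m^2 / (S - n m^2) >= T^2  <=>  m^2 >= T^2 S / (n(n-1+T^2))
    shape = diffs.shape[1:]
    flat = diffs.reshape(n, -1)
    sumsq = np.sum(flat**2, axis=0)
    thresh2 = t_crit**2 * sumsq / (n * (n - 1 + t_crit**2))
    means = (flips.astype(float) @ flat) / n
    scale = np.sqrt(n * (n - 1))
    for k in range(plan.n_perm):
        m = means[k]
        m2 = m * m
        denom = sumsq - n * m2
        supra = (m2 >= thresh2) & (denom > 0)
        if not supra.any():
            continue
        t_flat = np.zeros_like(m)
        idx = np.flatnonzero(supra)
        t_flat[idx] = scale * m[idx] / np.sqrt(denom[idx])
        t = t_flat.reshape(shape)
        null_max[k] = _max_mass(t, (t >= t_crit).reshape(shape))
        null_min[k] = -_max_mass(-t, (t <= -t_crit).reshape(shape))

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
        threshold=t_crit,
        shape=diffs.shape[1:],
    )
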