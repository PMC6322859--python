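"""Core data containers shared across the analysis stages.

Conventions used throughout the package:

* time is expressed in **seconds**, relative to the onset of the
  sentence-final word (SFW); word onsets precede the SFW at multiples of
  -1.0 s,
* sensor and source positions are expressed in **millimetres**,
* epoch arrays are ordered ``(trial, sensor, time)``,
* analysis windows are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TrialInfo",
    "EpochSet",
    "ForwardModel",
    "SimilarityTimeSeries",
    "CrossTemporalMatrix",
    "TopographicMap",
    "SourceMap",
    "WindowResult",
    "Cluster",
    "ClusterResult",
    "CovarianceEstimate",
    "BeamformerFilters",
    "SensorNeighborGraph",
    "window_mask",
]


def window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples falling in the half-open window [start, end)."""
    start, end = window
    if end < start:
        raise ValueError(f"window end {end} precedes start {start}")
    return (times >= start) & (times < end)


@dataclass(frozen=True)
class TrialInfo:
    """Metadata for one epoch (one sentence presentation).

    ``member_index`` distinguishes the two sentences of a pair; exactly one
    member of each pair ends with the contextually expected sentence-final
    word, the other with a plausible but unexpected one.
    """

    sentence_id: int
    pair_id: int
    member_index: int
    expectancy: str  # "expected" | "unexpected"
    category: str  # "noun" | "verb"
    presentation_position: int = -1

    def __post_init__(self) -> None:
        if self.member_index not in (1, 2):
            raise ValueError("member_index must be 1 or 2")
        if self.expectancy not in ("expected", "unexpected"):
            raise ValueError(f"unknown expectancy {self.expectancy!r}")
        if self.category not in ("noun", "verb"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class EpochSet:
    """Epoched multi-sensor time series for one participant.

    ``data`` has shape ``(n_trials, n_sensors, n_times)``; ``times`` is the
    shared, uniformly spaced time axis in seconds relative to SFW onset.
    """

    data: np.ndarray
    times: np.ndarray
    sensor_ids: list[str]
    trials: list[TrialInfo]
    participant: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, sensor, time)")
        n_trials, n_sensors, n_times = self.data.shape
        if len(self.trials) != n_trials:
            raise ValueError(
                f"{len(self.trials)} TrialInfo entries for {n_trials} trials"
            )
        if len(self.sensor_ids) != n_sensors:
            raise ValueError(
                f"{len(self.sensor_ids)} sensor ids for {n_sensors} sensors"
            )
        if self.times.shape != (n_times,):
            raise ValueError("times length does not match data")
        if n_times >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniformly spaced")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sample_rate(self) -> float:
        if self.n_times < 2:
            raise ValueError("sample rate undefined for < 2 samples")
        return 1.0 / (self.times[1] - self.times[0])

    def with_data(self, data: np.ndarray, times: np.ndarray | None = None) -> "EpochSet":
        """Copy of this EpochSet with new signal values (same metadata)."""
        return EpochSet(
            data=data,
            times=self.times if times is None else times,
            sensor_ids=list(self.sensor_ids),
            trials=list(self.trials),
            participant=self.participant,
        )

    def trial_index(self) -> dict[int, int]:
        """Map sentence_id -> row index in ``data``."""
        return {t.sentence_id: i for i, t in enumerate(self.trials)}


@dataclass
class ForwardModel:
    """Toy lead field: grid positions plus gain matrix.

    ``gain`` has shape ``(n_sensors, 3 * n_grid)``; columns ``3g..3g+2`` are
    the sensor fields of three orthogonal unit dipoles at grid point ``g``.
    """

    grid_positions: np.ndarray  # (G, 3) mm
    gain: np.ndarray  # (S, 3G)
    grid_spacing: float  # mm
    sensor_positions: np.ndarray | None = None  # (S, 3) mm

    def __post_init__(self) -> None:
        self.grid_positions = np.asarray(self.grid_positions, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if self.grid_positions.ndim != 2 or self.grid_positions.shape[1] != 3:
            raise ValueError("grid_positions must be (G, 3)")
        if self.gain.shape[1] != 3 * self.n_grid:
            raise ValueError("gain must have 3 columns per grid point")
        if np.any(np.all(self.gain == 0.0, axis=1)):
            raise ValueError("gain has an all-zero sensor row")

    @property
    def n_grid(self) -> int:
        return self.grid_positions.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    def leadfield(self, g: int) -> np.ndarray:
        """The (n_sensors, 3) lead field of grid point ``g``."""
        return self.gain[:, 3 * g : 3 * g + 3]


@dataclass
class SimilarityTimeSeries:
    """Correlation R(t) for one comparison or a condition average.

    Undefined samples (zero across-sensor variance in either pattern) are
    stored as NaN, never as zero.
    """

    r: np.ndarray
    times: np.ndarray
    label: str = ""
    n_comparisons: int = 1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.r.shape != self.times.shape:
            raise ValueError("r and times must align")
        finite = np.isfinite(self.r)
        if np.any(np.abs(self.r[finite]) > 1.0 + 1e-9):
            raise ValueError("correlation values outside [-1, 1]")


@dataclass
class CrossTemporalMatrix:
    """Time x time spatial-similarity matrix for one comparison/average.

    ``r[i, j]`` is the correlation between the first trial's sensor pattern
    at ``times_row[i]`` and the second trial's pattern at ``times_col[j]``.
    """

    r: np.ndarray
    times_row: np.ndarray
    times_col: np.ndarray
    label: str = ""
    n_comparisons: int = 1


@dataclass
class TopographicMap:
    """Per-sensor temporal-similarity values over an analysis window."""

    r_per_sensor: np.ndarray
    sensor_ids: list[str]
    label: str = ""
    window: tuple[float, float] = (0.0, 0.0)
    n_comparisons: int = 1


@dataclass
class SourceMap:
    """Per-grid-point temporal-similarity values (or condition difference)."""

    values: np.ndarray
    grid_positions: np.ndarray
    label: str = ""
    window: tuple[float, float] = (0.0, 0.0)


@dataclass
class WindowResult:
    """Window-averaged within/between comparison via a paired t-test."""

    interval: tuple[float, float]
    mean_r_within: float
    mean_r_between: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass
class Cluster:
    """One supra-threshold connected component and its mass statistic."""

    members: np.ndarray  # flat indices (cells / sensors / grid points)
    mass: float
    tail: str  # "positive" | "negative"
    p_value: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= 0.025)


@dataclass
class ClusterResult:
    """Clusters plus the max-mass permutation null they were tested against."""

    clusters: list[Cluster]
    null_max: np.ndarray  # max positive mass per permutation
    null_min: np.ndarray  # min negative mass per permutation
    n_perm: int
    threshold: float | tuple[float, float]
    shape: tuple[int, ...] = ()

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


@dataclass
class CovarianceEstimate:
    """Trial-averaged sensor covariance over an estimation window."""

    matrix: np.ndarray
    window: tuple[float, float]
    n_trials: int
    ill_conditioned: bool = False


@dataclass
class BeamformerFilters:
    """LCMV spatial filters, one 3 x n_sensors block per grid point."""

    filters: np.ndarray  # (G, 3, S)
    lam: float
    valid: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim != 3 or self.filters.shape[1] != 3:
            raise ValueError("filters must be (G, 3, S)")
        if self.valid.size == 0:
            self.valid = np.ones(self.filters.shape[0], dtype=bool)

    @property
    def n_grid(self) -> int:
        return self.filters.shape[0]


@dataclass
class SensorNeighborGraph:
    """Symmetric sensor adjacency from a Euclidean distance cutoff."""

    adjacency: np.ndarray  # (S, S) bool, no self-edges
    radius: float  # mm
    sensor_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency must have no self-edges")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @classmethod
    def from_positions(
        cls,
        positions: np.ndarray,
        radius: float,
        sensor_ids: Sequence[str] | None = None,
    ) -> "SensorNeighborGraph":
        positions = np.asarray(positions, dtype=float)
        d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
        adj = (d <= radius) & ~np.eye(len(positions), dtype=bool)
        ids = list(sensor_ids) if sensor_ids is not None else [
            f"S{i:03d}" for i in range(len(positions))
        ]
        return cls(adjacency=adj, radius=radius, sensor_ids=ids)
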