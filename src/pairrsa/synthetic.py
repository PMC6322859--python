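"""Synthetic epoched MEG with the paired-design statistical structure.

The generator emulates the structure the similarity analyses assume, for a
reading paradigm in which sentences are presented word by word (one word
per second) and epochs are time-locked to the onset of the sentence-final
word (SFW). Each simulated trial is a sum of three components:

* a **word-evoked component**: one spatial pattern times a transient
  waveform, time-locked to every word onset and identical across trials.
  It drives the general rise in spatial similarity that follows each word
  in *all* trial pairs and defines the supra-threshold analysis window,
* an **item-specific component**: per sentence pair, a spatial pattern and
  a temporal waveform shared by the two members of the pair and active
  only inside the effect window (default 120-515 ms after the onset of
  the penultimate word, i.e. -880 to -485 ms before SFW onset). In
  ``static`` mode the pattern is fixed; in ``dynamic`` mode it is redrawn
  every ``identity_tau`` seconds with a smooth crossfade, which confines
  cross-temporal generalization to the diagonal,
* additive Gaussian **noise** whose sensor covariance decays with
  inter-sensor distance (squared-exponential kernel), optionally with
  AR(1) temporal correlation.

Amplitudes are expressed in across-sensor standard deviations: every
spatial pattern is standardized to zero mean and unit variance across
sensors, and waveforms to unit RMS, so ``evoked_amplitude`` and
``identity_amplitude`` directly set signal-to-noise against ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal.windows import tukey

from .containers import EpochSet, ForwardModel, TrialInfo, window_mask
from .design import PairDesign, random_design

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_sensor_layout",
    "simulate_dataset",
    "make_forward_model",
    "simulate_from_sources",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-conditions configuration for the synthetic generator.

    Defaults mirror the emulated study: 26 participants, 120 sentence
    pairs, 269 sensors, 4 s epochs around SFW onset with word onsets every
    1000 ms, and an item-specific effect window of -880 to -485 ms.
    The working sample rate is 300 Hz (the rate of the cross-temporal
    analysis), configurable.
    """

    n_participants: int = 26
    n_pairs: int = 120
    n_sensors: int = 269
    sample_rate: float = 300.0
    epoch_window: tuple[float, float] = (-2.0, 2.0)
    word_onsets: tuple[float, ...] = (-2.0, -1.0, 0.0)
    effect_window: tuple[float, float] = (-0.880, -0.485)
    evoked_amplitude: float = 0.30
    identity_amplitude: float = 0.15
    identity_mode: str = "static"  # "static" | "dynamic"
    identity_tau: float = 0.050  # s; pattern lifetime in dynamic mode
    noise_sd: float = 1.0
    noise_spatial_scale: float = 30.0  # mm
    noise_ar1: float = 0.0
    sensor_radius: float = 100.0  # mm
    pattern_smooth_mm: float = 25.0
    evoked_onset: float = 0.120  # s after each word onset
    evoked_offset: float = 0.515  # s after each word onset
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_pairs, self.n_sensors) < 1:
            raise ValueError("counts must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        e0, e1 = self.epoch_window
        f0, f1 = self.effect_window
        if not (e0 < f0 < f1 < e1):
            raise ValueError(
                f"need epoch start {e0} < effect window ({f0}, {f1}) < epoch end {e1}"
            )
        if self.identity_mode not in ("static", "dynamic"):
            raise ValueError(f"unknown identity_mode {self.identity_mode!r}")
        if self.identity_tau <= 0:
            raise ValueError("identity_tau must be positive")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must lie in [0, 1)")

    def times(self) -> np.ndarray:
        start, end = self.epoch_window
        n = int(round((end - start) * self.sample_rate))
        return start + np.arange(n) / self.sample_rate


@dataclass
class GroundTruth:
    """What the generator embedded, for parameter-recovery tests."""

    config: SimulationConfig
    design: PairDesign
    sensor_positions: np.ndarray
    effect_window: tuple[float, float]
    effect_samples: np.ndarray  # sample indices inside the effect window
    # per participant: dict with keys "evoked_pattern", "identity_patterns",
    # "identity_waveforms" (and for source-level runs, "source_assignments")
    participants: list[dict] = field(default_factory=list)
    noise_covariance: np.ndarray | None = None

    def summary(self) -> dict:
        """JSON-serializable summary (no large arrays)."""
        return dict(
            n_participants=self.config.n_participants,
            n_pairs=self.config.n_pairs,
            n_sensors=self.config.n_sensors,
            sample_rate=self.config.sample_rate,
            effect_window=list(self.effect_window),
            identity_mode=self.config.identity_mode,
            evoked_amplitude=self.config.evoked_amplitude,
            identity_amplitude=self.config.identity_amplitude,
            noise_sd=self.config.noise_sd,
            seed=self.config.seed,
        )


def make_sensor_layout(
    n_sensors: int, seed: int, radius: float = 100.0, cap_fraction: float = 0.5
) -> np.ndarray:
    """3-D sensor positions (mm) on a spherical cap (helmet stand-in).

    Points follow a Fibonacci spiral over the cap (near-uniform coverage)
    with a small seeded jitter, re-projected onto the sphere; layouts are
    therefore deterministic per seed with strictly positive pairwise
    distances.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    if not 0 < cap_fraction <= 1:
        raise ValueError("cap_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    # cap covers z in [1 - cap_fraction, 1] of the unit sphere (hemisphere
    # by default); jitter ~5% of the nominal inter-sensor spacing
    z = 1.0 - cap_fraction * (np.arange(n_sensors) + 0.5) / n_sensors
    phi = _GOLDEN_ANGLE * np.arange(n_sensors)
    spacing = np.sqrt(2 * np.pi * cap_fraction / n_sensors)  # radians, approx
    z = z + rng.normal(0, 0.05 * spacing * cap_fraction, n_sensors)
    z = np.clip(z, -1.0, 1.0)
    phi = phi + rng.normal(0, 0.05 * spacing, n_sensors)
    rho = np.sqrt(1.0 - z**2)
    pts = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return pts


def _smooth_patterns(
    rng: np.random.Generator,
    n_patterns: int,
    positions: np.ndarray,
    smooth_mm: float,
) -> np.ndarray:
    """Random sensor patterns smoothed over the layout, standardized to
    zero mean / unit variance across sensors. Shape (n_patterns, S)."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    w = np.exp(-0.5 * d2 / smooth_mm**2)
    raw = rng.standard_normal((n_patterns, positions.shape[0]))
    pat = raw @ w.T
    pat -= pat.mean(axis=1, keepdims=True)
    sd = pat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pat / sd


def _evoked_waveform(config: SimulationConfig, times: np.ndarray) -> np.ndarray:
    """Word-locked transient: a tapered plateau (Tukey bump) from
    ``evoked_onset`` to ``evoked_offset`` after each word onset.

    The taper is short (alpha 0.15) so the window over which evoked-driven
    spatial similarity exceeds a detection threshold tracks the nominal
    onset/offset closely."""
    wave = np.zeros_like(times)
    for onset in config.word_onsets:
        lo, hi = onset + config.evoked_onset, onset + config.evoked_offset
        mask = window_mask(times, (lo, hi))
        n = int(mask.sum())
        if n > 0:
            wave[mask] = np.maximum(wave[mask], tukey(n, alpha=0.15))
    return wave


def _identity_waveforms(
    rng: np.random.Generator, n_pairs: int, n_win: int, rate: float
) -> np.ndarray:
    """Per-pair smooth random waveforms on the effect window, tapered to
    zero at the window edges and normalized to unit RMS."""
    raw = rng.standard_normal((n_pairs, n_win))
    # moving-average smoothing to ~20 ms correlation length
    half = max(1, int(round(0.020 * rate)))
    kernel = np.exp(-0.5 * (np.arange(-2 * half, 2 * half + 1) / half) ** 2)
    kernel /= kernel.sum()
    smoothed = np.apply_along_axis(
        lambda x: np.convolve(x, kernel, mode="same"), 1, raw
    )
    smoothed *= tukey(n_win, alpha=0.2)[None, :]
    rms = np.sqrt(np.mean(smoothed**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return smoothed / rms


def _dynamic_pattern_course(
    patterns: np.ndarray, n_win: int, rate: float, tau: float
) -> np.ndarray:
    """Time-resolved pattern (S, n_win) from a pattern sequence with a
    cosine crossfade every ``tau`` seconds (variance-preserving for
    near-orthogonal patterns)."""
    n_seg = patterns.shape[0] - 1
    seg_len = tau * rate
    t = np.arange(n_win)
    seg = np.minimum((t / seg_len).astype(int), n_seg - 1)
    frac = np.clip(t / seg_len - seg, 0.0, 1.0)
    theta = 0.5 * np.pi * frac
    course = (
        patterns[seg].T * np.cos(theta)[None, :]
        + patterns[seg + 1].T * np.sin(theta)[None, :]
    )
    return course


def _noise_chol(config: SimulationConfig, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor of the distance-decay spatial covariance, and the
    covariance itself."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    cov = config.noise_sd**2 * np.exp(-0.5 * d2 / config.noise_spatial_scale**2)
    jitter = 1e-8 * max(config.noise_sd**2, 1e-12)
    chol = np.linalg.cholesky(cov + jitter * np.eye(len(positions)))
    return chol, cov


def _simulate_noise(
    rng: np.random.Generator,
    chol: np.ndarray,
    n_trials: int,
    n_times: int,
    ar1: float,
) -> np.ndarray:
    s = chol.shape[0]
    white = rng.standard_normal((n_trials, s, n_times))
    if ar1 > 0.0:
        innov_sd = np.sqrt(1.0 - ar1**2)  # keeps unit marginal variance
        out = np.empty_like(white)
        out[..., 0] = white[..., 0]
        for t in range(1, n_times):
            out[..., t] = ar1 * out[..., t - 1] + innov_sd * white[..., t]
        white = out
    # spatial mixing: (S, S) @ (S, n_trials * n_times)
    mixed = chol @ white.transpose(1, 0, 2).reshape(s, -1)
    return mixed.reshape(s, n_trials, n_times).transpose(1, 0, 2)


def _base_components(config: SimulationConfig, design: PairDesign | None):
    if design is None:
        design = random_design(config.n_pairs, seed=config.seed)
    if design.n_pairs != config.n_pairs:
        raise ValueError("design pair count does not match config")
    times = config.times()
    eff_mask = window_mask(times, config.effect_window)
    if not eff_mask.any():
        raise ValueError("effect window contains no samples")
    ss = np.random.SeedSequence(config.seed)
    layout_seed, order_seed, *participant_seeds = ss.spawn(config.n_participants + 2)
    positions = make_sensor_layout(
        config.n_sensors,
        seed=int(layout_seed.generate_state(1)[0] % (2**31)),
        radius=config.sensor_radius,
    )
    # random presentation order (no separation constraints; the design
    # module provides constrained orders when they matter)
    order_rng = np.random.default_rng(order_seed)
    order = design.table["sentence_id"].to_numpy().copy()
    order_rng.shuffle(order)
    design = design.with_presentation_order(order)
    return design, times, eff_mask, positions, participant_seeds


def _trials_from_design(design: PairDesign) -> list[TrialInfo]:
    trials = []
    for _, row in design.table.sort_values("sentence_id").iterrows():
        trials.append(
            TrialInfo(
                sentence_id=int(row["sentence_id"]),
                pair_id=int(row["pair_id"]),
                member_index=int(row["member_index"]),
                expectancy=row["expectancy"],
                category=row["category"],
                presentation_position=int(row.get("presentation_position", -1)),
            )
        )
    return trials


def simulate_dataset(
    config: SimulationConfig, design: PairDesign | None = None
) -> tuple[list[EpochSet], GroundTruth]:
    """Generate one EpochSet per participant plus the embedded ground truth.

    Each trial is evoked + item-specific + noise as described in the module
    docstring; the two members of a pair receive identical item-specific
    patterns and waveforms.
    """
    design, times, eff_mask, positions, pseeds = _base_components(config, design)
    trials = _trials_from_design(design)
    n_trials = len(trials)
    n_win = int(eff_mask.sum())
    eff_idx = np.flatnonzero(eff_mask)
    chol, cov = (None, None)
    if config.noise_sd > 0:
        chol, cov = _noise_chol(config, positions)

    ew = _evoked_waveform(config, times)
    pair_row = {p: k for k, p in enumerate(design.pair_ids)}

    epoch_sets: list[EpochSet] = []
    truth = GroundTruth(
        config=config,
        design=design,
        sensor_positions=positions,
        effect_window=config.effect_window,
        effect_samples=eff_idx,
        noise_covariance=cov,
    )
    sensor_ids = [f"MEG{i:03d}" for i in range(config.n_sensors)]

    for pi, pseed in enumerate(pseeds):
        rng = np.random.default_rng(pseed)
        evoked_pattern = _smooth_patterns(rng, 1, positions, config.pattern_smooth_mm)[0]
        waveforms = _identity_waveforms(rng, config.n_pairs, n_win, config.sample_rate)

        data = np.zeros((n_trials, config.n_sensors, len(times)))
        data += config.evoked_amplitude * evoked_pattern[None, :, None] * ew[None, None, :]

        if config.identity_mode == "static":
            patterns = _smooth_patterns(
                rng, config.n_pairs, positions, config.pattern_smooth_mm
            )
            ident = (
                config.identity_amplitude
                * patterns[:, :, None]
                * waveforms[:, None, :]
            )  # (pairs, S, n_win)
        else:
            n_seg = int(np.ceil(n_win / (config.identity_tau * config.sample_rate))) + 1
            patterns = _smooth_patterns(
                rng, config.n_pairs * n_seg, positions, config.pattern_smooth_mm
            ).reshape(config.n_pairs, n_seg, config.n_sensors)
            ident = np.empty((config.n_pairs, config.n_sensors, n_win))
            for k in range(config.n_pairs):
                course = _dynamic_pattern_course(
                    patterns[k], n_win, config.sample_rate, config.identity_tau
                )
                ident[k] = config.identity_amplitude * course * waveforms[k][None, :]

        for ti, tr in enumerate(trials):
            data[ti][:, eff_idx] += ident[pair_row[tr.pair_id]]

        if config.noise_sd > 0:
            data += _simulate_noise(rng, chol, n_trials, len(times), config.noise_ar1)

        epoch_sets.append(
            EpochSet(
                data=data,
                times=times,
                sensor_ids=sensor_ids,
                trials=trials,
                participant=pi,
            )
        )
        truth.participants.append(
            dict(
                evoked_pattern=evoked_pattern,
                identity_patterns=patterns,
                identity_waveforms=waveforms,
            )
        )
    return epoch_sets, truth


def make_forward_model(
    n_grid: int,
    sensor_positions: np.ndarray,
    seed: int,
    grid_spacing: float = 10.0,
    interior_radius_fraction: float = 0.7,
) -> ForwardModel:
    """Toy forward model: a regular grid inside the sensor shell with a
    smooth dipolar-falloff gain.

    The gain of grid point ``p`` for orientation ``e_k`` at sensor ``s`` is
    ``e_k . (r_s - p) / |r_s - p|^3`` (the field gradient of a monopole
    potential) — spatially smooth across sensors and generically rank 3
    per grid point. Each 3-column block is normalized to unit Frobenius
    scale; rank-deficient blocks trigger a seeded position jitter and,
    failing that, a diagnostic error.
    """
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    sensor_positions = np.asarray(sensor_positions, dtype=float)
    radius = float(np.linalg.norm(sensor_positions, axis=1).mean())
    rmax = interior_radius_fraction * radius
    rng = np.random.default_rng(seed)

    # regular lattice inside a sphere, ordered by distance from the centre
    half = int(np.ceil(rmax / grid_spacing))
    axis = np.arange(-half, half + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.linalg.norm(lattice, axis=1) <= rmax
    lattice = lattice[inside]
    if len(lattice) < n_grid:
        raise ValueError(
            f"lattice with spacing {grid_spacing} mm holds only "
            f"{len(lattice)} points inside radius {rmax:.0f} mm; "
            f"{n_grid} requested"
        )
    dist = np.linalg.norm(lattice, axis=1)
    order = np.lexsort((lattice[:, 2], lattice[:, 1], lattice[:, 0], dist))
    grid = lattice[order[:n_grid]].astype(float)
    # sub-mm seeded jitter keeps layouts distinguishable across seeds
    grid = grid + rng.normal(0.0, 0.1, grid.shape)

    def gain_for(points: np.ndarray) -> np.ndarray:
        diff = sensor_positions[:, None, :] - points[None, :, :]  # (S, G, 3)
        r3 = np.linalg.norm(diff, axis=-1) ** 3
        g = diff / r3[:, :, None]  # column k = component k of the falloff field
        g = g.reshape(len(sensor_positions), -1)
        return g

    gain = gain_for(grid)
    for gidx in range(n_grid):
        block = gain[:, 3 * gidx : 3 * gidx + 3]
        for attempt in range(3):
            sv = np.linalg.svd(block, compute_uv=False)
            if sv[-1] > 1e-10 * sv[0]:
                break
            grid[gidx] += rng.normal(0.0, 0.5, 3)
            block = gain_for(grid[gidx : gidx + 1])
            gain[:, 3 * gidx : 3 * gidx + 3] = block
        else:
            raise RuntimeError(f"grid point {gidx}: rank-deficient lead field")
        gain[:, 3 * gidx : 3 * gidx + 3] = block / (np.linalg.norm(block) / np.sqrt(3))
    return ForwardModel(
        grid_positions=grid,
        gain=gain,
        grid_spacing=grid_spacing,
        sensor_positions=sensor_positions,
    )


def simulate_from_sources(
    forward: ForwardModel,
    source_assignments: dict[int, tuple[int, Sequence[float]]],
    config: SimulationConfig,
    design: PairDesign | None = None,
) -> tuple[list[EpochSet], GroundTruth]:
    """Like :func:`simulate_dataset` but item-specific waveforms are
    injected at assigned grid points and projected through the gain.

    ``source_assignments`` maps pair_id -> (grid index, orientation); the
    orientation is fixed per grid point and the projected sensor pattern is
    standardized across sensors, so ``identity_amplitude`` keeps the same
    meaning as at sensor level. Pairs without an assignment receive no
    item-specific signal.
    """
    if forward.sensor_positions is None:
        raise ValueError("forward model lacks sensor positions")
    if forward.n_sensors != config.n_sensors:
        raise ValueError("forward model sensor count does not match config")
    patterns_by_pair: dict[int, np.ndarray] = {}
    for pair_id, (gidx, orient) in source_assignments.items():
        if not 0 <= gidx < forward.n_grid:
            raise ValueError(f"grid index {gidx} out of range")
        o = np.asarray(orient, dtype=float)
        if o.shape != (3,) or np.linalg.norm(o) == 0:
            raise ValueError("orientation must be a nonzero 3-vector")
        o = o / np.linalg.norm(o)
        pat = forward.leadfield(gidx) @ o
        sd = pat.std()
        if sd == 0:
            raise ValueError(f"grid point {gidx}: zero projected pattern")
        patterns_by_pair[pair_id] = (pat - 0.0) / sd  # keep mean: pattern is physical

    design2, times, eff_mask, _, pseeds = _base_components(config, design)
    # the forward model fixes the sensor geometry; reuse its positions
    positions = forward.sensor_positions
    trials = _trials_from_design(design2)
    n_trials = len(trials)
    n_win = int(eff_mask.sum())
    eff_idx = np.flatnonzero(eff_mask)
    chol, cov = (None, None)
    if config.noise_sd > 0:
        chol, cov = _noise_chol(config, positions)
    ew = _evoked_waveform(config, times)
    sensor_ids = [f"MEG{i:03d}" for i in range(config.n_sensors)]

    epoch_sets: list[EpochSet] = []
    truth = GroundTruth(
        config=config,
        design=design2,
        sensor_positions=positions,
        effect_window=config.effect_window,
        effect_samples=eff_idx,
        noise_covariance=cov,
    )
    for pi, pseed in enumerate(pseeds):
        rng = np.random.default_rng(pseed)
        evoked_pattern = _smooth_patterns(rng, 1, positions, config.pattern_smooth_mm)[0]
        waveforms = _identity_waveforms(rng, config.n_pairs, n_win, config.sample_rate)
        data = np.zeros((n_trials, config.n_sensors, len(times)))
        data += config.evoked_amplitude * evoked_pattern[None, :, None] * ew[None, None, :]
        pair_row = {p: k for k, p in enumerate(design2.pair_ids)}
        for ti, tr in enumerate(trials):
            if tr.pair_id in patterns_by_pair:
                w = waveforms[pair_row[tr.pair_id]]
                data[ti][:, eff_idx] += (
                    config.identity_amplitude * np.outer(patterns_by_pair[tr.pair_id], w)
                )
        if config.noise_sd > 0:
            data += _simulate_noise(rng, chol, n_trials, len(times), config.noise_ar1)
        epoch_sets.append(
            EpochSet(data=data, times=times, sensor_ids=sensor_ids, trials=trials,
                     participant=pi)
        )
        truth.participants.append(
            dict(
                evoked_pattern=evoked_pattern,
                identity_waveforms=waveforms,
                source_assignments=dict(source_assignments),
                source_patterns=patterns_by_pair,
            )
        )
    return epoch_sets, truth
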