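# Methods

This note documents the models, statistics and numerical choices behind
`pairrsa`, and what its synthetic-data validation does and does not show.

## Design and comparison sets

A design of N sentence pairs has 2N sentences; each pair's two members
predict the same sentence-final word (SFW), one member actually ending
with it (expected) and the other not (unexpected). Comparisons are
unordered sentence pairs — correlation is symmetric, so each enters once:
N within-pair and 2N(N−1) between-pair comparisons (28,560 for N = 120).
Control subsets: a seeded uniform between-pair subsample matched in count
to the within-pairs; between-pairs sharing the penultimate word (SFW-1)
with the within-pairs of the pairs involved; a partition of pairs by
whether the expected-SFW member was presented first; and same-syntactic-
category cross-pair comparisons. The within-category set excludes
within-pair comparisons by default (they share the item, not merely its
category); an inclusive variant is available via a flag because the
narrower reading is not the only defensible one.

Presentation orders must keep pair members at least `min_separation`
sentences apart (default 30) with at most `max_run` (default 3)
same-expectancy sentences in a row. Pure rejection sampling is hopeless
at the design scale — a uniform shuffle of 240 sentences has ≈ 31
expected separation violations — so orders are built by seeded shuffle
followed by random swaps accepted only when they do not increase the
violation count, bounded by an attempt budget. Every emitted order is
valid by construction; the test suite re-validates with an independent
brute-force scan.

## Similarity statistics

Spatial similarity at time t is the Pearson correlation across sensors
of two trials' instantaneous pattern vectors; temporal similarity at a
sensor is the Pearson correlation over window samples of the two trials'
time courses. Internally each vector is centered and unit-normed so any
correlation is a dot product, and all pairwise comparisons per
participant reduce to one batched Gram matrix product. Zero-variance
vectors give undefined correlations; these propagate as NaN and are
excluded from averages with counts logged — never imputed as zero.
Condition averages are arithmetic means of raw R values (no Fisher z; a
z option exists but is off by default, matching the averaging convention
the analysis emulates).

The analysis window is detected on the *combined* series (mean of the
within and between group averages), as the longest contiguous run above
R = 0.04 inside the search interval (one word before the SFW); 0.03 is
the documented sensitivity setting. The window-averaged within−between
difference is a two-sided paired t over participants, df = n − 1.

Cross-temporal matrices correlate one member's pattern at time i with
the other member's at time j after resampling to 300 Hz; the correlation
surface is smoothed along both time axes with a truncated Gaussian (40 ms
support read as the full kernel length, SD 8 ms, renormalized at the
edges so constants are preserved). Smoothing along both axes is the
default; one-axis smoothing is available. The unsmoothed diagonal equals
the similarity time series on the resampled axis by construction. For
condition averages the smoothing is applied to the per-participant mean
surface, which equals smoothing each comparison's surface by linearity.
Between-pair matrix averages use one seeded draw of N between-pairs
matched to the N within-pairs.

## Cluster permutation tests

All cluster tests share one exchangeability scheme: swapping the
within/between labels inside a participant equals flipping the sign of
that participant's difference, so the null is built from seeded
per-participant sign flips, taking the largest cluster mass per
permutation. p = (b + 1)/(n_perm + 1) — never zero, minimum ≈ 0.001 at
1000 permutations — and clusters in the highest or lowest 2.5% of the
null are significant (two-sided at 5%).

* Matrix test: per-cell paired t; cells beyond the two-sided p ≤ 0.05
  quantile form 4-connected (edge-adjacent) clusters; mass = Σt. The
  adjacency choice is ours; nothing in the emulated procedure specifies
  it. For speed the permutation null exploits the flip-invariance of the
  per-cell sum of squares: each permuted t matrix follows from a single
  mean recomputation, and the t threshold becomes a closed-form bound on
  the flipped mean.
* Sensor/grid test: statistic = group-mean difference per node;
  cluster-forming threshold = its 95th percentile across nodes (5th for
  the negative tail), *recomputed inside every permutation* so the
  observed statistic and the null are computed identically — required
  for exchangeability, and decided here since the emulated description
  is silent. Clusters form in the sensor neighborhood graph (Euclidean
  radius, default 40 mm) or among contiguous grid points (within one
  grid-spacing step). A percentile threshold always admits some nodes,
  so the mere existence of clusters is uninformative; inference rests
  entirely on the max-mass null. The percentile is taken over sensors of
  the group-mean difference (not participants × sensors), the more
  natural reading of a group-level thresholding rule.

The 2×2 repeated-measures ANOVA (Order × Pairs) is computed via
difference scores: with one df per factor each effect is a paired t on a
per-participant contrast, F = t², df (1, n−1), partial η² = F/(F+n−1).
It is cross-checked against pingouin in the tests.

## LCMV beamformer

W_g = (L_gᵀC⁻¹L_g)⁻¹L_gᵀC⁻¹ with C the trial-averaged sensor covariance
(per-trial mean removed) over the estimation window (default: SFW-1
onset to 1000 ms after SFW onset), pooled over all trials per
participant (a per-condition covariance is a possible alternative; the
pooled choice avoids condition-dependent filters). Regularization is
C + λ·mean(diag C)·I with λ = 0 by default and an automatic 5% loading
when C's condition number exceeds 1e8 (logged as a warning). At λ = 0
the unit-gain identity W_g L_g = I₃ holds to 1e−8 and the output is the
minimum-variance solution — diagonal loading can only raise output
variance (the test suite checks exactly this direction). Orientation
selection concatenates each grid point's 3 × T output over the
participant's trials and projects onto the first left singular vector
(sign fixed: largest-magnitude entry positive); per-trial concatenation
is available as a switch. Grid points with a singular constrained system
are flagged invalid and excluded downstream. The 85%-of-maximum peak
region reports cluster members reaching ≥ 0.85 of the cluster's maximum
difference.

The forward model is deliberately a toy: grid points on a 10 mm lattice
inside the sensor shell, with gain columns given by a smooth dipolar
falloff field — generically rank 3 per point and spatially smooth, which
is all the beamformer algebra requires. It makes no claim to head
geometry, and anatomical labeling is out of scope.

## Synthetic generator

Each trial is evoked + item-specific + noise:

* **Evoked**: one spatial pattern per participant times a Tukey-tapered
  plateau (taper fraction 0.15) from 120 to 515 ms after every word
  onset (words at −2, −1, 0 s; SOA 1 s). Shared by all trials, it
  produces the word-locked rise in spatial similarity for *all*
  comparisons that defines the supra-threshold window. The short taper
  makes the threshold crossing track the nominal support closely.
* **Item-specific**: per pair, a spatial pattern and a smooth random
  waveform (≈ 20 ms correlation length, unit RMS, tapered to zero at the
  window edges), identical for both pair members and exactly zero
  outside the effect window (−880 to −485 ms). `static` mode holds the
  pattern fixed; `dynamic` mode redraws it every τ (default 50 ms) with
  a cosine crossfade, which confines cross-temporal generalization to
  |lag| ≲ τ and reproduces diagonal-limited generalization.
* **Noise**: Gaussian with squared-exponential distance-decay sensor
  covariance (default SD 1, spatial scale 30 mm), white in time by
  default with an optional AR(1) switch.

Patterns are standardized to zero mean and unit variance across sensors
and waveforms to unit RMS, so amplitudes are in across-sensor-SD units.
Defaults — 26 participants, 120 pairs, 269 sensors, 300 Hz, 4 s epochs,
evoked amplitude 0.30, identity amplitude 0.15, noise SD 1 — were chosen
analytically so the condition-average similarity lands near the
plausible empirical scale for this paradigm (within ≈ 0.087, between
≈ 0.070 in simulation) and the direction of all effects is recoverable;
no quantitative claim about real effect sizes is intended. The working
rate is 300 Hz rather than an acquisition-grade 1200 Hz because the
cross-temporal analysis operates at 300 Hz anyway. Sensor layouts are
Fibonacci spirals on a hemispheric shell (radius 100 mm) with small
seeded jitter. All randomness flows from one `SeedSequence`, so identical
config + seed gives bit-identical datasets.

Validation problem sizes are deliberately desk-scale choices: null and
recovery simulations use 12 participants, 40 pairs and 64 sensors with
epochs restricted to the second before the SFW (where all tested
quantities live); source-recovery runs use 6 participants, 20 pairs,
64 sensors, a 27-point grid and identity amplitude 0.3 — a focal
single-source configuration needs the higher amplitude because its
variance competes with beamformer leakage across the grid.

What passing tests show: the statistics are correctly implemented
(oracle agreement, exact count identities, calibrated false-positive
rates) and can recover effects with the embedded structure. What they do
not show: robustness to real MEG nuisance structure — eye/cardiac
artifacts, head movement, 1/f and oscillatory background, sensor noise
heterogeneity, realistic forward fields — none of which the generator
emulates.

## Known limitations

* The forward model and noise model are structural stand-ins, not
  physical simulations; source-space conclusions are about the algebra
  and statistics, not localization accuracy in real heads.
* Noise is temporally white by default; autocorrelated noise widens the
  similarity-series correlation length and the effective degrees of
  freedom of window averages (the AR(1) switch exists for exploring
  this).
* Full-scale default simulation (26 × 240 trials × 269 sensors × 1200
  samples) holds ≈ 620 MB per participant in memory; analyses at that
  scale should process participants one at a time.
* `read_epochs_fif` imports signal and timing but cannot reconstruct
  pair metadata from event codes alone; a design table must be joined
  separately.
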