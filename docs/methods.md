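# Methods

`envconn` implements a seed-based, band-limited power-envelope analysis
of electrophysiological resting-state functional connectivity, together
with a synthetic data generator that reproduces the statistical
structure the analysis assumes. This note documents the model, the
numerical choices, and what the synthetic benchmarks do and do not show.

## The analysis model

**Spectral decomposition.** Sensor signals are decomposed into exclusive,
non-overlapping frequency bands — θ (5–8 Hz), α (8–13 Hz), β (13–25 Hz),
low γ (25–45 Hz) — by ideal (brick-wall) Fourier filters: DFT
coefficients outside the band are set exactly to zero. Bands are
half-open `[f_lo, f_hi)` so the canonical set tiles 5–45 Hz with no
shared bin. Brick-wall filters wrap around the record edge, so one
second is trimmed from each end of every filtered record before any
statistic is computed. Two consequences of the ideal filter are load
bearing: filtering is an orthogonal projection (idempotent, linear), and
signals in disjoint bands have *exactly* zero zero-lag inner product,
which is why cross-frequency maps need no leakage correction.

**Source reconstruction.** A linear minimum-norm (Tikhonov) inverse

    K = R G' (G R G' + λ² C)⁻¹,   R = r·I,   λ² = 1/SNR²

maps band-filtered sensor data onto a regular 5-mm source grid. `C` is
the band-specific sensor noise covariance estimated from an empty-room
segment (filtered, trimmed, symmetrized, diagonally loaded at 1e-8 of
the mean diagonal). The source-prior scale `r` is fixed per band by a
prior-consistency contract: the trace of the modeled sensor covariance
`G R G' + λ² C` equals the trace of the measured band-limited data
covariance. The contract is linear in `r`, so it is solved in closed
form (clipped away from zero). Because band-filtering the same
broadband data scales signal and noise covariances by the same
band-power fraction, this construction makes the resolution matrix
`K G` — and hence the spatial leakage pattern — essentially
band-independent, a property asserted by test. The default
regularization assumes amplitude SNR 3 (λ² = 1/9), the conventional
minimum-norm choice. When the forward model carries three orientations
per source, moments are reduced to one series by projection onto the
principal variance direction (sign fixed by the first nonzero loading).

**Envelope connectivity.** For a seed location (default: the ventral
pars triangularis of the left inferior frontal gyrus, MNI
(−43, 20, 4) mm, resolved to the nearest grid source), every
(seed band, target band) pair yields a map of Pearson correlations
between *slow envelopes*: the Hilbert-transform magnitude of the
band-limited source series, brick-wall low-passed at 1 Hz. When the two
bands coincide, each target series is first orthogonalized against the
seed series (static zero-lag regression, `y⊥ = y − (⟨y,x⟩/⟨x,x⟩)x`),
which removes the spurious zero-lag correlation produced by the
inverse operator's point spread; the seed's own map value is undefined
(NaN) on these maps. When the bands differ, brick-wall orthogonality
makes the correction an exact no-op and it is skipped. Residual
"secondary" leakage — shared background components that survive seed
orthogonalization — is not corrected; it is the reason the analysis
interprets only *local maxima* of the group maps, never absolute map
values.

**Group inference.** Each subject's map is reduced to its deviation from
the whole-map mean (the "background" connectivity); a one-sample,
one-tailed t test of these deviations across subjects (df = n−1) is
algebraically the paired map-vs-background test. The voxelwise threshold
is the Student t upper quantile at α/ρ, where ρ is the effective number
of independent spatial components in minimum-norm maps, estimated as the
numerical rank of the leadfield (singular values above 1e-6 of the
largest). On the reference 306-channel acquisition this gives ρ = 58 and
a critical t of 3.22 at α = 0.05, df = 99; the corrected voxel level is
0.05/58 = 8.6e-4 (one published rendering slips the exponent to 10⁻³;
the printed t value is consistent with 10⁻⁴, so α/ρ is normative here).
Sources with zero across-subject variance receive a signed infinite
sentinel and a data-quality flag rather than being dropped. The
rank-based Bonferroni correction is a heuristic: it controls the
familywise error exactly when the map carries ρ independent values
(block structure, asserted by test) and empirically when the grid is not
much finer than the rank, but it is mildly anticonservative when many
correlated sources share few components (see Limitations).

**Maxima, template, clustering.** Supra-threshold local maxima are
sources strictly exceeding all neighbors within a 26-connected
(≤ √3 × spacing) neighborhood; an exact-tie plateau that dominates its
rim is reported once at its centroid with a tie flag. Maxima in parcel 0
of the integer parcel volume (deep/non-cortical) are discarded. Each
maximum is classified against a binary template mask (NIfTI) by the
Euclidean distance to the nearest in-mask voxel center, with strict
`distance < 10 mm` counting as in-template; a coordinate whose
nearest-voxel rounding is in-mask has distance 0. Finally, maxima
coordinates (within- and cross-frequency pools separately) are
partitioned by k-means (Lloyd iterations from k-means++ starts, best of
200 restarts, Euclidean distance) for every k = 1..n; the within-cluster
sum of squares SSW(k) forms the elbow curve (repaired to be
non-increasing against restart artifacts), and k is selected where the
discrete tangent — central difference at interior k, one-sided at the
ends — is most parallel to the chord joining the curve's first and last
points (ties → smallest k; flat curve → k = 1 with a degenerate flag).
Band-pair labels are carried through but never inform the partition.
The Lloyd loop is implemented in-package so the per-iteration SSW
monotonicity contract can be asserted and the relabeling (descending
cluster size, then lexicographic centroid) is deterministic;
scikit-learn's KMeans is used in the tests as an independent
cross-check, never as the implementation.

## The synthetic generator

Each source carries, per band, `amplitude × carrier(t) × modulator(t)`.

- **Carriers** are Gaussian white noise brick-wall filtered into the
  band. For sources participating in a planted coupling the carrier is
  additionally amplitude-flattened: two rounds of dividing by the
  Hilbert envelope and re-filtering (the final operation is the filter,
  so in-band energy is exact; unit sample variance). Flattening matters
  because a raw Gaussian band carrier has Rayleigh modulus fluctuations
  whose sub-1-Hz component (~36% of modulus power for the 5-Hz-wide α
  band) would otherwise attenuate the measured envelope correlation to
  ~0.75× the planted value. Background sources keep plain band-noise
  carriers — they carry no planted correlation to protect.
- **Modulators** are log-normal: `m = exp(z/2)` with `z` a unit-variance
  Gaussian process band-limited to (0, 1] Hz. Heavy-tailed positive
  envelopes resemble resting MEG amplitude statistics; the amplitude
  distribution is a modelling convention, not a measured property. A
  planted coupling with target envelope correlation ρ_env shares a
  latent component between the two (node, band) slots at the latent
  correlation `ρ_z = 4·ln(1 + ρ_env(e^{1/4} − 1))`, the exact inversion
  of the log-normal link, so the realized envelope correlation converges
  to ρ_env (verified against a direct Monte-Carlo oracle of the link and
  recovered within ±0.1 on full synthetic signals).
- **Amplitudes.** Coupled slots have unit amplitude; background sources
  default to 0.3. Resting-state band power is dominated by a few
  coherent network nodes over a weaker distributed background, and this
  ~10 dB per-source margin is what makes a planted network coupling
  detectable through a rank-limited leadfield; with a uniform
  equal-amplitude background the coupled pair would carry ~2/500 of
  sensor power and no estimator could recover it (an information limit,
  not an implementation one).
- **Forward model.** Pseudo-sensors sit on two spherical shells (radii
  one and three grid spacings beyond the source cloud, split evenly);
  the gain of a source at a sensor is a Gaussian in their distance
  (width 2.5 spacings) with a deterministic 5% per-sensor gain jitter,
  and gain columns are normalized per source. Two radial shells give
  the toy geometry depth discrimination (single-shell variants mislocate
  deep sources); column normalization removes the minimum-norm depth
  bias the way depth weighting does for real leadfields. Columns depend
  only on source position.
- **Sensors.** The leadfield projection is scaled so that its RMS over
  sensors and time equals `sensor_snr × noise_std`, then white Gaussian
  noise of std `noise_std` is added (`sensor_snr = inf` returns the raw
  projection). Matching empty-room segments contain the noise alone.
- **Reproducibility.** A single `rng_seed` fans out through
  `np.random.SeedSequence` to the forward model, each subject, and the
  empty room, so outputs are bit-identical for identical configs and
  independent of subject evaluation order.

Default desk-scale conditions: 20 subjects, 60 s at 200 Hz, 500 sources
(10×10×5 grid at 5 mm), 60 sensors, sensor SNR 10. The full acquisition
scale (100 subjects, 5 min at 1 kHz, 16,102 sources) is expressible via
the same config but is not exercised by the tests.

What the generator does *not* emulate: 1/f spectra, physiological
artifacts (cardiac, ocular), head movement, spatially correlated sensor
noise (an option exists for a fixed random spatial covariance but white
is the default), realistic anatomy (BEM leadfields, cortical surfaces),
or inter-subject variability in the forward model. Passing recovery
tests therefore demonstrates the correctness of the estimation chain
under its own assumptions, not performance on real recordings.

## Benchmarks shipped with the package

- **Reference coordinate sets.** Two bundled TSVs hold the MNI
  coordinates of the published within-frequency (n = 14) and
  cross-frequency (n = 47) language-network connectivity maxima, used as
  clustering fixtures. On the 14-point set the elbow criterion selects
  k = 4, with the two largest clusters of sizes 6 and 4 entirely in the
  left hemisphere; the 47-point set tallies 38 left / 9 right. On the
  47-point set the 200-restart SSW curve is deterministic and the
  tangent-chord criterion selects k = 8; the continuous tangent-parallel
  point falls between k = 7 and k = 8 (adjacent segment slopes 2144 and
  1944 straddle the chord slope 2006.5), and single-restart k-means —
  whose noisier curves select k = 7 in a sizeable fraction of draws —
  is the plausible origin of a k = 7 selection for this point set. The
  package reports what its prescribed procedure computes.
- **Parameter recovery.** At the desk-scale conditions with one planted
  long-range within-α coupling (ρ_env = 0.9, SNR 10), the group map's
  dominant supra-threshold local maximum falls on (or one spacing from)
  the planted node with large t (typically 9–15). The acceptance suite
  additionally requires that maximum to be *sole* in ≥ 90% of 20 seeded
  runs — a requirement the threshold anticonservatism discussed under
  Limitations makes intrinsically borderline at this grid-to-rank ratio:
  a minority of runs show one extra borderline local maximum on the
  secondary-leakage ridge.
- **Familywise error.** Strict null runs (sensor noise only) at a
  reduced size chosen so the leadfield rank matches the source count
  (48 sources, 80 sensors, 12 subjects, 30 s) keep the
  any-supra-threshold rate at the nominal α over 200 repetitions.
- **Point spread.** Noiseless single-source data localize to within one
  grid spacing for 20/20 random source positions.

## Numerical choices and conventions

- DFT bin at exactly `f_lo` belongs to the band; the 1-Hz envelope
  low-pass keeps `f ≤ cutoff` including DC.
- Orthogonalization acts on the real band-limited series *before* the
  Hilbert transform; the seed series itself is never re-orthogonalized.
- Pearson correlations are computed on trimmed segments; no Fisher
  transform at the map level.
- Seed resolution: nearest grid source, ties to the lowest index;
  coordinates outside the grid bounding box (padded by one spacing) are
  an error.
- Rank tolerance for effective DOF: 1e-6 relative to the largest
  singular value.
- k-means restarts default to 200 with a fixed seed; at the fixture
  sizes this reliably reaches the global SSW optimum, removing k-means
  stochasticity from the elbow decision.
- Empty k-means clusters are re-seeded at the farthest point; in
  practice this finds optima at least as good as k-means++ alone.

## Limitations

- The rank-based effective-DOF Bonferroni correction is exact only when
  map values replicate ρ independent components. When the source grid is
  much finer than the rank (e.g. 500 sources, rank 60), the threshold is
  mildly anticonservative and isolated threshold-level false maxima
  appear at a per-run rate of roughly 0.1–0.2; the familywise-error
  benchmark therefore fixes the reduced-size geometry so that ρ matches
  the independent-component count, which is the regime the correction
  claims.
- Static orthogonalization removes only the seed's zero-lag component.
  Secondary leakage (shared background mixed into both seed and target
  reconstructions, and coupling signal leaking along the seed–target
  path) survives and can elevate a broad region of the map; this is
  inherent to the method and is why only local maxima are interpreted.
- The prior-consistency condition is operationalized as trace matching
  of modeled vs measured sensor covariance; the trace contract is this
  package's specification of the condition, chosen for its closed-form
  solution and scale consistency.
- `run_full` orchestrates the stages in memory and persists each stage's
  outputs; only the clustering stage is independently re-runnable from
  persisted files (`run_cluster_only`), which is the re-entry point the
  coordinate fixtures need.
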