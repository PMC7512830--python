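# Methods

This note documents the models and procedures implemented in `fcgbnet`,
the parameters that matter, the numerical choices that were genuinely
open, and what the synthetic-data tests do and do not establish.

## Sliding-window connectivity

Windows of length L = `window_mult` × SL samples (default 10 × SL) slide
in steps of SL. SL defaults to one second of data (`round(fs)` samples),
which places the entropy series on a 1 Hz grid; it is user-settable for
other time scales. Epoch k (1-based) covers samples [1+m, L+m] with
m = (k−1)·SL and is stamped with its window-start time (k−1)·SL/fs.
Incomplete tail windows are dropped — zero-padding would bias the
correlations of the final epoch downward. The number of epochs is
floor((N−L)/SL)+1; one hour at 300 Hz with SL = 300 gives exactly 3591
epochs, the last at 3590 s.

The edge weight is the absolute normalized equal-time cross-correlation
of the raw windowed signals: a plain inner product, no mean removal. For
band-limited, near-zero-mean EEG the difference from a Pearson
correlation is negligible, but the raw form is the definition implemented;
`pearson=True` (CLI `--pearson`) switches to the mean-centered variant
for users who expect it. The full lag machinery (τ ≥ 0 summation and the
τ < 0 mirror rule) exists and is tested, but the pipeline always uses
τ = 0. A window in which some channel has exactly zero energy raises an
error naming the channel rather than emitting NaN.

## Network entropy

Edge weights are read row-major from the strict upper triangle (the order
is irrelevant to the entropy, which is a symmetric function; it is fixed
only so dumps are reproducible). Normalization pins the probability sum to
1 exactly by adjusting the last element within one ulp. Entropy uses the
continuity convention 0·log 0 = 0. An all-zero graph (entropy undefined)
raises rather than propagating NaN into the time-frequency stage.
Entropy is computed on the weighted matrices; binarization exists only
for the classical comparison metrics. Bounds 0 ≤ NE_k ≤ log2 n hold by
construction and are asserted in tests, including the majorization
property (concentrating mass never raises entropy).

## Binarization and classical metrics

The threshold search walks the grid {1, 1−s, …, s} (s = 0.01 by default)
and accepts the first (largest) T whose binary graph — edge iff weight
strictly exceeds T — is connected, judged by λ₂ > 10⁻⁹ of the
combinatorial Laplacian L = D − A computed on the *binary* adjacency
(a weighted Laplacian would make the search circular). T = 0 is not on
the grid: it would admit every positive weight however small, defeating
the purpose of discarding weak links. When no positive grid point
connects the graph the step is divided by 10, down to `binarize_min_step`
(10⁻⁴); a graph still disconnected then is reported unconnectable. The
strict inequality means a uniform-0.8 graph binarizes at T = 0.79, not
0.80 — the likeliest off-by-one-grid-step discrepancy between
implementations, so it is pinned by tests. The 10⁻⁹ eigenvalue tolerance
is safe because binary Laplacians of small graphs have spectral gaps many
orders larger.

Clustering, characteristic path length and global efficiency are
delegated to networkx (and independently cross-checked against a
hand-rolled BFS oracle in the tests). Vulnerability — for which no single
canonical formula exists — is implemented as the maximal relative drop in
global efficiency over single-node deletions, with the efficiency of the
reduced graph computed over the remaining pairs (0 if fewer than two
nodes remain); the 5-node star therefore has vulnerability exactly 1.
Per-epoch metric rows for unconnectable epochs are emitted as NaN and
logged, never fatal.

## Preprocessing

Band selection keeps one dyadic detail band of a multilevel DWT (discrete
Meyer wavelet). The depth is derived from the sampling rate and the
requested band and non-dyadic requests are rejected outright — at 300 Hz
the band 18.75–37.5 Hz is exactly the level-3 detail band, and silent
approximation would hide misconfiguration. Artifact correction zeroes,
per channel and per pass, every retained-band coefficient strictly above
mean(C) + 2·std(C); two passes by default. The rule is one-sided on the
signed coefficient values (the literal reading of "greater than the
threshold"); `use_abs=True` offers the symmetric |C| variant, since the
intent is ambiguous. The std is the population definition — immaterial at
these coefficient counts but fixed for reproducibility. Statistics are
computed per channel, never pooled across channels. Reconstruction uses
the corrected band alone, so output energy never exceeds input energy.

## Time-frequency transform

The entropy series rides on a large offset (near log2 171 ≈ 7.418 bits),
so it is mean-removed before the transform (`keep_dc` disables this).
The transform is a frequency-domain CWT: the discrete Meyer wavelet has
no closed form, so its waveform is sampled once by the cascade algorithm,
its spectrum Ψ(ν) computed with heavy zero-padding and phase-centered at
the waveform's magnitude peak, and coefficients obtained as
irfft(X(f)·conj(Ψ(a f))). Evaluating one precomputed spectrum at a·f for
every scale a avoids per-scale kernel resampling noise — important
because Meyer's spectral peak is a plateau flat to ~10⁻⁴ over ±1%, where
independent per-scale errors would make the power-maximal scale hop
between neighboring bins. For the same reason the center frequency used
in the pseudo-frequency map f = f_c/(a·dt) is the argmax of that same
sampled spectrum (≈ 0.678 cycles per unit), keeping the map and the
transform's response peak consistent by construction.

The signal is extended periodically (plain length-K DFT). For a
mean-removed series the wrap discontinuity is small, the wavelet's zero
mean annihilates DC exactly, and a pure tone's per-scale power becomes an
exact sample of |Ψ|² — which is what makes frequency localization
grid-accurate. Edge trust is described by the stored cone-of-influence
half-widths; detection does not mask it by default.

Scales form a geometric grid of `n_scales` (1024) pseudo-frequencies from
min(0.5 Hz, Nyquist of the entropy series) down to a floor that defaults
to the lowest resolvable frequency: two full cycles over the record
(2·fs_ne/K), capped at f_max/16. Slower components cannot complete a
cycle in the data and contribute only broad, unlocalizable smears. A
warning is emitted when the configured band maximum disagrees with the
Nyquist implied by SL. Power is the squared coefficient; no baseline
normalization is applied.

## Event detection and matching

Power is averaged over the scales whose pseudo-frequency falls in the
band of interest (0–0.1 Hz default; full-band collapse available since
higher-frequency components also carry localization information). The
threshold is a percentile of this envelope itself — scale-free and
unit-free. The default percentile is 90: the supra-threshold budget must
match the expected density of transient events, and with events arriving
roughly every 90–100 s (the regime the generator reproduces) and wavelet
smears tens of seconds wide, event-affected epochs approach 10% of the
series; a 95th-percentile budget is exhausted by the strongest, widest
blobs and drops weaker events entirely. The percentile is exposed
(`--detect-percentile`) for sparser or denser regimes. A corollary of
thresholding the envelope against itself is that an event-free recording
still yields a handful of low-power "regions" (the top decile of
background always exists); what separates them from real events is their
power, orders of magnitude below event blobs, not their count.

Maximal supra-threshold runs become regions; the centerline is the
power-weighted temporal centroid (a midpoint variant is available).
Each recorded event is matched to the nearest centerline, ties to the
earlier region, without exclusivity — one region may serve several
events and events are never discarded. Errors are extracted − recorded;
with window-start epoch timestamps the entropy valley of an event of
duration d leads its center by roughly (L/fs − d)/2 + d/2 ≈ 5 s under
defaults, a visible negative bias well inside the ±10 s tolerance. The
Pearson correlation between recorded and extracted times is computed on
matched pairs only, and only when at least three pairs with nonzero
variance exist.

## Synthetic generator

Channels are mixtures c_i = a(t)·s + sqrt(1−a(t)²)·η_i of one shared
band-limited source and independent band-limited noises (4th-order
Butterworth band-pass, 18.75–37.5 Hz, unit-variance normalized), so
a(t)² is both the shared-variance fraction and the expected pairwise
correlation. Baseline a² = 0.7; inside each 8 s event window it ramps
(1 s cosine ramps) to 0.1. Defaults mirror the target recording geometry:
19 channels labelled with the 10–20 montage, 300 Hz, 600 s, six events.
The rank-1 (single shared source) design is deliberate: the entropy
statistic responds to the concentration of the edge-weight distribution,
and modulating one global coupling is the simplest mechanism that
produces entropy valleys with analytically interpretable ground truth.
Events modulate coupling, not amplitude; a separate `artifact_times_s`
option injects high-amplitude bursts so the thresholding stage is
exercised independently.

What passing tests show: the pipeline recovers global decorrelation
transients with second-scale accuracy under realistic correlation noise.
What they do not show: performance on real EEG, whose 1/f background,
non-stationary coupling topology, volume-conduction structure and
ocular/cardiac artifacts the generator deliberately does not model.

## Problem sizes used in the self-checks

The acceptance script and tests use the generator's native conditions
(19 × 300 Hz × 600 s, six events) for the end-to-end check; oracle
comparisons use 50 random windows (≤ 8 channels, ≤ 64 samples), 200
random weighted graphs (≤ 12 nodes) for the threshold search and 30 for
the metric oracles; tone and impulse localization use 600- and 400-epoch
series. These sizes give exact or near-exact checks while keeping the
whole suite fast on one CPU.

## Known limitations

- Sensor-space connectivity only; no leakage or source-space correction.
- The raw (non-centered) correlation makes results sensitive to DC
  offsets in the input; remove offsets upstream or use `pearson=True`.
- Periodic extension in the CWT assumes the series' ends are at
  comparable levels; a strong trend would create wrap artifacts at the
  record edges (inside the cone of influence).
- The percentile detector reports relative prominence, not statistical
  significance; region power should be compared against a null or
  baseline recording when absolute claims are needed.
- EDF reading requires uniform per-channel sampling rates.
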