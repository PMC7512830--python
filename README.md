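# fcgbnet

Network entropy for the sequence analysis of dynamic EEG functional
connectivity graphs.

`fcgbnet` is for researchers who study how the brain's functional network
reorganizes during long, single-trial recordings — e.g., tracking fatigue-
related events during an hour of simulated driving — where trial averaging
is impossible and sensor-space connectivity is noisy and leakage-prone.
Instead of following individual edges, it tracks a single scalar per
sliding window: the Shannon entropy of the graph's edge-weight
distribution, which responds to global reorganization of interactive
information while being insensitive to which particular edges carry it.

## Method

For a recording with E channels, a window of length L = 10·SL samples
slides in steps of SL (one second of data by default). In window (epoch)
k, the functional connectivity matrix **F** has entries

    γ_ij = | CC(s_i, s_j)(0) | / sqrt( CC(s_i,s_i)(0) · CC(s_j,s_j)(0) ),

the absolute normalized equal-time cross-correlation of channels i and j
(raw lagged inner product, no mean removal), with the diagonal set to zero.
The n = E(E−1)/2 upper-triangular weights are normalized to probabilities
p_i = γ_i / Σγ, and the network entropy of the epoch is

    NE_k = − Σ_i p_i log2 p_i     (bits),

maximal at log2 n when weight is spread evenly and lower when it
concentrates. The per-epoch series NE_k (sampled at fs/SL = 1 Hz under
defaults) is mean-removed and decomposed with a continuous wavelet
transform (discrete Meyer wavelet, 1024 scales tiling 0–0.5 Hz) into a
power scalogram. High-power regions of the 0–0.1 Hz band envelope are
extracted, each summarized by its power-weighted temporal centerline, and
matched to recorded events; timing errors use the extracted time as
minuend (error = extracted − recorded).

For comparison, each weighted graph can be binarized at the largest
threshold T for which the binary graph stays connected (second-smallest
Laplacian eigenvalue λ₂ > 0, searched from T = 1 downward in steps of
0.01, refined ×10 when too coarse), and four classical metrics are
computed on it: average clustering coefficient, characteristic path
length, global efficiency and vulnerability.

A synthetic-data module generates 19-channel, 300 Hz recordings in which
all channels share one band-limited source (18.75–37.5 Hz); transient
drops of the shared-variance fraction at known times produce ground-truth
decorrelation events for validating the whole chain.

## Worked example

```
python examples/02_synthetic_pipeline.py
```

prints

```
recording: 19 ch x 180000 samples at 300 Hz
entropy series: 591 epochs, range 7.333-7.417 bits
high-power regions detected: 6
   recorded_s  extracted_s  error_s
0        85.7        80.52    -5.18
1       171.4       166.19    -5.21
2       257.1       252.48    -4.62
3       342.9       337.94    -4.96
4       428.6       423.93    -4.67
5       514.3       509.46    -4.84
within 10 s: 100.0%   Pearson r = 1.00000
```

The entropy stays near its 7.418-bit maximum (log2 171) at baseline and
dips when coupling drops; all six implanted events are localized within
10 s of their true times (epochs carry window-start times, hence the small
negative bias), and the extracted times correlate with the implanted ones
at r ≈ 1. The other scripts in `examples/` demonstrate the entropy
statistic itself, the binarization + classical metrics, and the artifact
preprocessing stage.

## Command line

```
fcgb-netent simulate --spec spec.json --out simdir/
fcgb-netent run --eeg simdir/recording.csv --events simdir/events.tsv \
    --fs 300 --out results/ --no-preprocess
fcgb-netent metrics --eeg simdir/recording.csv --fs 300 --out results/
```

`run` writes `ne_series.csv`, `scalogram.npy` + `scalogram_axes.csv`,
`regions.csv`, `matches.csv` and `summary.json`. EDF input is detected by
the `.edf` suffix; delimited matrices (channels × samples) need `--fs`.

## Documentation

`docs/methods.md` describes the model, its assumptions, the tunable
parameters, the numerical design choices and known limitations.
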