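"""End-to-end run on a synthetic recording with implanted events.

Generates a 19-channel, 300 Hz, 600 s recording in which channel coupling
transiently drops at six known times, runs the full pipeline (sliding
window connectivity -> network entropy -> scalogram -> region detection ->
event matching) and prints the per-event timing errors.
"""

from fcgbnet import AnalysisConfig, SynthSpec, generate, run_pipeline

spec = SynthSpec(seed=0)  # defaults: 19 ch, 300 Hz, 600 s, 6 events
rec, events = generate(spec)
print(f"recording: {rec.n_channels} ch x {rec.n_samples} samples at {rec.fs:g} Hz")

result = run_pipeline(rec, AnalysisConfig(), events=events, preprocess=False)

print(f"entropy series: {len(result.ne)} epochs, "
      f"range {result.ne.values.min():.3f}-{result.ne.values.max():.3f} bits")
print(f"high-power regions detected: {len(result.regions)}")
print(result.matches.rows[["recorded_s", "extracted_s", "error_s"]].round(2))
s = result.matches.summary
print(f"within 10 s: {100 * s['frac_within_10s']:.1f}%   "
      f"Pearson r = {s['pearson_r']:.5f}")

# error_s = extracted - recorded: negative errors mean the entropy feature
# (the valley caused by the coupling drop) appears slightly before the
# recorded event center, because epochs are stamped with window-start times.
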