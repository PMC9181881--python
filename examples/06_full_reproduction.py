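"""Run the full pipeline over all standard presets and compare every
recovered quantity against the generator's encoded ground truth."""

from helmkit import RunManifest, run_reproduction

manifest = RunManifest(seed=0, n_photons=1_000_000)
report = run_reproduction(manifest)

print(report.comparison.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print(
    "\nall quantities within tolerance:" if report.all_within_tolerance
    else "\nWARNING -- deviations above tolerance:",
    report.all_within_tolerance,
)
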