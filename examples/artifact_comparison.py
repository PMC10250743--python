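"""Device robustness to artifacts: textile vs dry headband.

Runs the scripted 9-action artifact-induction session for a 10-subject
cohort with both device profiles and applies the per-band paired Wilcoxon
comparison. The textile device's higher contact impedance shows up as
significantly higher broadband power under artifacts and a higher 45-55 Hz
(mains) band everywhere.
"""

from texeeg import bandpass, compute_psd, make_cohort, \
    simulate_artifact_session
from texeeg.spectral import band_comparison_table, band_power_table
from texeeg.synthetic import default_device_profiles

devices = default_device_profiles()
spectra = {}
for i, profile in enumerate(make_cohort(10, seed=5)):
    for dev_name, dev in devices.items():
        rec, _ = simulate_artifact_session(profile, dev, seed=100 * i + 1)
        rec = bandpass(rec, 0.1, 100.0)
        spectra[(f"S{i + 1:02d}", dev_name, "artifact")] = compute_psd(rec)

table = band_power_table(spectra)
comparison = band_comparison_table(table, "artifact")
print(comparison.to_string(index=False))
print("\ndirection +1 means the textile garment shows higher power; "
      "p-values are exact paired Wilcoxon across the 10 subjects.")
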