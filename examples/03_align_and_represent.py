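"""Turn corrected spectra into comparable feature vectors.

The alignment window theta comes from the data: each interior lock mass is
left out of the correction in turn and the worst deviation of its member
peaks gives a per-lock-mass window; theta is the 95th percentile.  Alignment
points detected at theta (lock-mass detection with the everyone-present rule
relaxed) become the feature columns.
"""

from vlmalign import (
    AlignmentModel,
    DetectionParams,
    SyntheticConfig,
    correct_set,
    detect_vlms,
    generate,
    represent_set,
)

spectra, truth = generate(SyntheticConfig(m=30, seed=42))
vlms = detect_vlms(spectra, DetectionParams.from_ppm(40.0))
corrected, _ = correct_set(spectra, vlms)

model = AlignmentModel.fit(spectra, corrected, vlms, percentile_z=95.0, noise_floor=1000.0)
print(f"leave-one-out deviations: {model.thetas_i.size} lock masses, "
      f"range {model.thetas_i.min()*1e6:.2f}-{model.thetas_i.max()*1e6:.2f} ppm")
print(f"theta = {model.theta_ppm:.2f} ppm (95th percentile)")
print(f"{len(model.points)} alignment points "
      f"(vs {len(vlms)} lock masses: sample-specific compounds add columns)")

features = represent_set(corrected, model)
print(f"\nfeature matrix: {features.shape[0]} samples x {features.shape[1]} points")
print(features.iloc[:3, :4].round(1))

# Each cell is the intensity of the corrected peak falling in that alignment
# point's window (0 when the compound is absent from the sample).  This
# matrix is the hand-off to any downstream statistics or classifier.
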