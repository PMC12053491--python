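"""Simulate a wild-type-like and an arrhythmic culture, then detect rhythms.

Generates two synthetic backscatter traces — one with a sustained 24 h
oscillation on a growth trend, one with trend and red noise only — and runs
the full analysis (detrend, smooth, wavelet significance, Fourier period).
"""

from circascan import PipelineConfig, SyntheticConfig, generate_series, run_pipeline

for name, cfg in [
    ("wild-type-like", SyntheticConfig(seed=11)),
    ("arrhythmic", SyntheticConfig.null_like(seed=11)),
]:
    report = run_pipeline(generate_series(cfg), PipelineConfig())
    s = report.summary
    print(f"{name}:")
    print(f"  rhythmic in 18-32 h band : {s['is_rhythmic']}")
    print(f"  wavelet best period (h)  : {s['best_wavelet_period_h']}")
    print(f"  Fourier period (h)       : {s['fourier_period_h']}")
    print(f"  detected peaks           : {s['n_peaks']}")

print()
print("A rhythmic culture shows in-band wavelet power above the red-noise")
print("95% level and a Fourier period near 24 h; the arrhythmic culture is")
print("declared not rhythmic even though a (meaningless) in-band spectral")
print("maximum can always be found.")
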