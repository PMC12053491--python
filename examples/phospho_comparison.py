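"""Compare a clock-protein phosphorylation cycle with the backscatter rhythm.

Builds a synthetic KaiC3 phosphorylation-ratio time course (two technical
replicates sampled every 1.5 h over one day) whose cycle peaks ~6.5 h
before the backscatter oscillation, fits the standard degree-5 polynomial
to the replicate means, and compares the fitted phospho peak with the
nearest backscatter peak.
"""

import numpy as np

from circascan import SyntheticConfig, fit_phospho, generate_series, preprocess
from circascan.preprocessing import find_peaks
from circascan.phase import _wrap

# backscatter rhythm peaking at multiples of 24 h
backscatter = generate_series(SyntheticConfig(seed=8, noise_sigma=0.05))
smoothed = preprocess(backscatter).smoothed
bs_peaks = find_peaks(smoothed, min_separation_h=12.0, prominence=1.0)

# phospho ratios peaking 6.5 h earlier than the 72 h backscatter peak
rng = np.random.default_rng(4)
times = np.arange(58.0, 82.1, 1.5)
true_peak = 72.0 - 6.5
cycle = 0.35 + 0.35 * np.cos(2 * np.pi * (times - true_peak) / 24.0)
replicates = np.column_stack([cycle, cycle]) + rng.normal(0, 0.02, (times.size, 2))
replicates = np.clip(replicates, 0, 1)

fit = fit_phospho(times, replicates)
nearest_bs = min(bs_peaks, key=lambda p: abs(p - fit.fitted_peak_time_h))
delay = _wrap(nearest_bs - fit.fitted_peak_time_h, 24.0)

print(f"fitted phospho peak       : {fit.fitted_peak_time_h:.2f} h (truth {true_peak} h)")
print(f"nearest backscatter peak  : {nearest_bs:.2f} h")
print(f"backscatter delay         : {delay:+.2f} h")
print()
print("A positive delay means the phosphorylation rhythm phase-advances the")
print("backscatter rhythm: the clock-state readout peaks hours before the")
print("optical proxy of cell state does.")
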