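"""Extract the three band-peak features from epochs of two tasks.

Shows that f1 (the top alpha-band PSD peak) separates a high-alpha class
from a low-alpha class, while f2 >= f3 always holds by construction.
"""

import numpy as np

from bandpeak import (
    TaskSpectralProfile, extract_bandpeak_features, generate_trials,
    lowpass_filter, segment_trials, welch_psd,
)

profiles = [
    TaskSpectralProfile("RS", 3.0, 10.0, 1.0, 18.0, 0.7, 24.0, 1.0, (1.0,)),
    TaskSpectralProfile("MA", 1.0, 10.5, 1.0, 18.0, 0.7, 24.0, 1.0, (1.0,)),
]
trials = generate_trials(profiles, n_trials_per_task=20, seed=1)

values = {"RS": [], "MA": []}
for epoch in segment_trials([lowpass_filter(t) for t in trials]):
    fv = extract_bandpeak_features(welch_psd(epoch))
    values[epoch.task_label].append(fv.values)

for task, rows in values.items():
    mean = np.mean(rows, axis=0)
    print(f"task {task}: mean f1={mean[0]:6.2f}  f2={mean[1]:5.2f}  f3={mean[2]:5.2f} "
          f"({len(rows)} epochs)")

print("\nf1 scales with the square of the alpha amplitude (PSD is quadratic "
      "in amplitude),\nso the 3x amplitude class shows a ~9x larger f1; f2/f3 "
      "barely move because the\nbeta parameters are identical between the classes.")
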