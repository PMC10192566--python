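"""From raw recordings to model-ready tensors.

Runs the fixed conditioning pipeline — band-pass filter, per-channel
min-max scaling, 1-s segmentation, Mexican-hat scalograms for the ECG —
and prints the resulting array shapes and label counts.
"""

import numpy as np

from seizefuse import build_dataset, generate_patient
from seizefuse.presets import scaled_preprocess, scaled_synthetic_spec

spec = scaled_synthetic_spec(seed=7)
dataset = build_dataset(generate_patient(spec), scaled_preprocess())

print(f"segments: {dataset.n_segments}")
print(f"EEG windows:     {dataset.eeg.shape}   (segments x channels x samples)")
print(f"ECG scalograms:  {dataset.scalogram.shape}   (segments x scales x pooled time)")
print(f"class labels:    {np.bincount(dataset.y)}  (interictal, preictal)")
print(f"episode labels:  {np.bincount(dataset.d)}  (segments per episode)")
print(f"EEG value range: [{dataset.eeg.min():.3f}, {dataset.eeg.max():.3f}] "
      "(min-max scaled per channel per recording)")
print("\nEach 1-s window carries a class label y (0 interictal, 1 preictal) "
      "and an episode label d used by the adversarial discriminators.")
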