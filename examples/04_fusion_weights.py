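"""Error-rate-driven fusion weights, step by step.

Evaluates the weight formula w_i = 1 + arctan((1 - err_i)/err_i) on a few
branch error-rate pairs and shows how the fused probability shifts toward
the more reliable branch.
"""

import numpy as np

from seizefuse import dynamic_weights, fixed_weights, fuse_decisions

print("err1   err2   ->  W1      W2")
for err1, err2 in [(0.5, 0.5), (0.1, 0.3), (0.01, 0.4), (0.0, 0.5)]:
    w = dynamic_weights(err1, err2)
    print(f"{err1:4.2f}   {err2:4.2f}   -> {w.W1:.4f}  {w.W2:.4f}")

p_eeg = np.array([[0.80, 0.20]])   # EEG branch: confident interictal
p_ecg = np.array([[0.40, 0.60]])   # ECG branch: leaning preictal

for label, w in (("fixed 0.5/0.5", fixed_weights()),
                 ("dynamic, err 0.1/0.3", dynamic_weights(0.1, 0.3))):
    fused = fuse_decisions(p_eeg, p_ecg, w)
    cls = "interictal" if fused[0, 0] >= fused[0, 1] else "preictal"
    print(f"{label}: fused p = {np.round(fused[0], 4)} -> {cls}")

print("\nA lower error rate earns a larger weight (arctan of the odds of "
      "being correct), so the better-validated branch dominates the fused "
      "decision while the weaker branch still contributes.")
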