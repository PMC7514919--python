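"""Segmentation similarity across a noise-degraded phantom series.

Generates noise-degraded phantoms spanning a range of SNRs, segments each
with Otsu thresholding with and without q-sigmoid preprocessing, and scores
every segmentation against the 3-sigma truth disc with the similarity index
S (average of the Jaccard overlap and the clean-ring fraction).
"""

import numpy as np

from qsigmoid import dispatch_params, noisy_phantom_series, run_noise_similarity

series = noisy_phantom_series(n=10, snr_max=100.0, seed=0)
p = dispatch_params(q=0.1, beta=1.0, alpha=0.8, lam=1.0)
records = run_noise_similarity(series, p, segmenter="otsu")

raw = [r.value for r in records if not r.params["preprocessed"]]
pre = [r.value for r in records if r.params["preprocessed"]]
print(f"{'snr':>8} {'S raw':>8} {'S preprocessed':>15}")
for (img, truth, snr), r, q in zip(series, raw, pre):
    print(f"{snr:8.2f} {r:8.4f} {q:15.4f}")
print(f"\nmean S raw          : {np.mean(raw):.4f}")
print(f"mean S preprocessed : {np.mean(pre):.4f}")
print()
print("S = 1 means the segmentation matches the truth disc exactly and stays")
print("clear of its one-pixel outer ring; 0.5 is an empty segmentation.  The")
print("broad q-sigmoid (q = 0.1, alpha = 0.8) is a monotone remap on this")
print("phantom, so it shifts Otsu's operating point rather than the ranking.")
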