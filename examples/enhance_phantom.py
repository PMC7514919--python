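"""Highlight the bright core of the Gaussian phantom with a q-sigmoid.

Builds the default 256x256 phantom (peak 1 at pixel (175, 175), spread 30 px),
applies the q < 1 deformed bell targeting intensity beta = 1 with a narrow
band alpha = 0.03, extracts the achieved region and scores it against the
3-sigma ground-truth disc.
"""

import numpy as np

from qsigmoid import (
    TransformParams,
    apply_transform,
    default_threshold,
    err_measure,
    extract_region,
    gaussian_scene,
    ground_truth_mask,
)

phantom = gaussian_scene()
truth = ground_truth_mask()

p = TransformParams(beta=1.0, alpha=0.03, lam=1.0, q=0.7)
out = apply_transform(phantom, p)
mask = extract_region(out, default_threshold(p.resolved_family(), "display"),
                      largest_component=True)
err = err_measure(mask, truth)

print(f"family resolved        : {p.resolved_family()}")
print(f"output range           : [{out.pixels.min():.4f}, {out.pixels.max():.4f}]")
print(f"achieved region pixels : {mask.sum()}")
print(f"convex-hull Err        : {err:.4f}")
print()
print("Err = 1 - A1/A0 compares hull areas of the achieved and true regions;")
print("0 is perfect overlap, values near 1 mean the highlighted core is far")
print("smaller than the 3-sigma target disc.")
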