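"""Pre-align a stack to a single refined global reference.

All particles are aligned to the running global average for a fixed number
of refinement iterations (default 14); the average sharpens as particles
come into register, which shows as a rising mean correlation peak.
"""

import numpy as np

from isac2d import SearchGrid, make_synthetic_stack, prealign

stack, truth = make_synthetic_stack(
    n_classes=1, n_per_class=80, box=32, snr=2.0, max_shift=3,
    mirror_allowed=False, seed=3,
)
grid = SearchGrid.for_box(32, s_max=3, mirror=False)
result = prealign(stack, grid, n_iters=14)

hits = sum(
    result.params["sx"][i] == truth.true_transform[i].sx
    and result.params["sy"][i] == truth.true_transform[i].sy
    for i in range(stack.n)
)
print("mean peak per iteration:",
      " ".join(f"{p:.3f}" for p in result.mean_peak_history))
print(f"shifts recovered exactly: {hits}/{stack.n}")
print(f"global average: {result.global_average.shape}, "
      f"masked mean {result.global_average.mean():.4f}")
# The mean peak is non-decreasing; with a mirror-free stack and matching
# search, essentially all ground-truth shifts are recovered exactly.
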