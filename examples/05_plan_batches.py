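"""Plan memory-budgeted batches for out-of-core alignment.

The planner sizes the largest particle batch whose working set (images,
polar spectra, cross-correlation table, outputs) fits 95% of the budget,
splits the stack evenly across workers, and cycles reference batches
inside particle batches so each particle is loaded once per pass.
"""

from isac2d import SearchGrid, estimate_batch_memory, plan_batches

grid = SearchGrid.for_box(64, s_max=3)
n, k = 100_000, 200

for stage in ("prealign", "multiref", "assigned"):
    kwargs = {"class_sizes": [500] * 200} if stage == "assigned" else {}
    plan = plan_batches(
        n, k, grid, box=64, budget_bytes=4 * 1024**3, g_workers=2,
        stage=stage, **kwargs,
    )
    est = estimate_batch_memory(plan.m, k if stage == "multiref" else 1, grid, 64)
    print(f"{stage:9s}: batch m={plan.m:6d}  est {est / 1e6:7.1f} MB  "
          f"workers {len(plan.worker_subsets)}  "
          f"ref batches {len(plan.reference_batches)}")
# Pre-alignment and the assigned stage use a single-reference table, so
# their batches are far larger than the multi-reference stage at k=200.
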