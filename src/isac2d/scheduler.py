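"""Memory-budgeted batch planning for out-of-core alignment.

The alignment stages differ in how their cross-correlation storage grows:
pre-alignment uses a single reference (small table), multi-reference
alignment grows with the number of references (batched over particles
with reference sub-batches cycled innermost, so each particle is loaded
only once per pass), and the assigned/stability stage batches whole
classes so each particle is loaded once per iteration set.  A closed-form
byte estimate sizes the largest particle batch that fits a configurable
fraction (default 95%) of the memory budget, and worker subsets split the
stack evenly for an in-process pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polar_align import PARAMS_DTYPE, SearchGrid, align_assigned, align_multiref

DEFAULT_MEMORY_FRACTION = 0.95
DEFAULT_BUDGET_BYTES = 2 * 1024**3

__all__ = [
    "BatchPlan",
    "estimate_batch_memory",
    "plan_batches",
    "run_multiref_batched",
    "run_assigned_batched",
    "DEFAULT_MEMORY_FRACTION",
    "DEFAULT_BUDGET_BYTES",
]


def estimate_batch_memory(
    m: int,
    k: int,
    grid: SearchGrid,
    box: int,
    element_size: int = 8,
) -> int:
    """Closed-form byte estimate for one aligner batch of m particles.

    Terms, each times ``element_size`` (8 for float64):

    * input images:            m * b^2
    * particle polar spectra:  m * S * M * R * F * 2   (complex)
    * reference polar spectra: k * R * F * 2           (complex)
    * cross-correlation table: m * k * S * M * A
    * output parameter tuples: m * k * 5

    with S shifts, M mirror branches (2 if the mirrored search is on),
    R rings, A angular samples and F = A/2 + 1 rFFT frequencies.
    """
    if min(m, k, box) < 1:
        raise ValueError("m, k and box must be positive")
    S = grid.n_shifts
    M = grid.n_mirror
    R = len(grid.ring_radii)
    A = grid.n_angular
    F = A // 2 + 1
    terms = (
        m * box * box
        + m * S * M * R * F * 2
        + k * R * F * 2
        + m * k * S * M * A
        + m * k * 5
    )
    return int(terms * element_size)


def _memory_terms(m: int, k: int, grid: SearchGrid, box: int) -> dict[str, int]:
    S, M, R, A = grid.n_shifts, grid.n_mirror, len(grid.ring_radii), grid.n_angular
    F = A // 2 + 1
    return {
        "input images": m * box * box,
        "particle spectra": m * S * M * R * F * 2,
        "reference spectra": k * R * F * 2,
        "ccf table": m * k * S * M * A,
        "output params": m * k * 5,
    }


@dataclass(frozen=True)
class BatchPlan:
    """How a stack streams through the aligner under a memory budget."""

    n: int
    k: int
    m: int
    stage: str
    worker_subsets: tuple[tuple[int, int], ...]  # (start, stop) per worker
    particle_batches: tuple[tuple[tuple[int, int], ...], ...]  # per worker
    reference_batches: tuple[tuple[int, int], ...]
    class_batches: tuple[tuple[int, ...], ...] = ()
    memory_fraction: float = DEFAULT_MEMORY_FRACTION
    budget_bytes: int = DEFAULT_BUDGET_BYTES

    def validate(self, grid: SearchGrid, box: int) -> None:
        covered = []
        for (lo, hi), batches in zip(self.worker_subsets, self.particle_batches):
            got = [i for a, b in batches for i in range(a, b)]
            if got != list(range(lo, hi)):
                raise AssertionError("particle batches do not partition the subset")
            covered.extend(got)
        if covered != list(range(self.n)):
            raise AssertionError("worker subsets do not partition 0..n-1")
        sizes = [hi - lo for lo, hi in self.worker_subsets]
        if max(sizes) - min(sizes) > 1:
            raise AssertionError("worker subsets are not even")
        k_batch = max(hi - lo for lo, hi in self.reference_batches)
        cap = self.memory_fraction * self.budget_bytes
        if estimate_batch_memory(self.m, k_batch, grid, box) > cap:
            raise AssertionError("planned batch exceeds the memory budget")


def plan_batches(
    n: int,
    k: int,
    grid: SearchGrid,
    box: int,
    budget_bytes: int = DEFAULT_BUDGET_BYTES,
    g_workers: int = 1,
    stage: str = "multiref",
    memory_fraction: float = DEFAULT_MEMORY_FRACTION,
    class_sizes: list[int] | None = None,
) -> BatchPlan:
    """Plan particle/reference batches that fit the memory budget.

    ``stage`` is one of prealign (k = 1), multiref (full n x k table;
    reference batches cycled inside particle batches) or assigned
    (k-independent table; whole classes per batch, requires
    ``class_sizes``).  Raises a capacity error naming the dominant memory
    term when even a single particle with a single reference does not fit.
    """
    if stage not in ("prealign", "multiref", "assigned"):
        raise ValueError(f"unknown stage {stage!r}")
    if n < 1 or g_workers < 1:
        raise ValueError("n and g_workers must be positive")
    cap = memory_fraction * budget_bytes
    k_eff = 1 if stage in ("prealign", "assigned") else k
    if estimate_batch_memory(1, 1, grid, box) > cap:
        terms = _memory_terms(1, 1, grid, box)
        worst = max(terms, key=terms.get)
        raise ValueError(
            f"memory budget too small for a single particle; "
            f"dominant term: {worst} ({terms[worst] * 8} bytes)"
        )
    # largest reference batch that admits at least one particle
    k_batch = k_eff
    while k_batch > 1 and estimate_batch_memory(1, k_batch, grid, box) > cap:
        k_batch -= 1
    # largest particle batch at that reference batch size
    lo_m, hi_m = 1, n
    while lo_m < hi_m:
        mid = (lo_m + hi_m + 1) // 2
        if estimate_batch_memory(mid, k_batch, grid, box) <= cap:
            lo_m = mid
        else:
            hi_m = mid - 1
    m = lo_m

    bounds = np.linspace(0, n, g_workers + 1).astype(int)
    worker_subsets = tuple(
        (int(bounds[w]), int(bounds[w + 1])) for w in range(g_workers)
    )
    particle_batches = tuple(
        tuple(
            (lo + off, min(lo + off + m, hi))
            for off in range(0, hi - lo, m)
        )
        for lo, hi in worker_subsets
    )
    reference_batches = tuple(
        (off, min(off + k_batch, k_eff)) for off in range(0, k_eff, k_batch)
    )
    class_batches: tuple[tuple[int, ...], ...] = ()
    if stage == "assigned":
        if class_sizes is None:
            raise ValueError("assigned stage requires class_sizes")
        class_batches = _pack_classes(class_sizes, m)
    plan = BatchPlan(
        n=n,
        k=k,
        m=m,
        stage=stage,
        worker_subsets=worker_subsets,
        particle_batches=particle_batches,
        reference_batches=reference_batches,
        class_batches=class_batches,
        memory_fraction=memory_fraction,
        budget_bytes=budget_bytes,
    )
    plan.validate(grid, box)
    return plan


def _pack_classes(class_sizes: list[int], m: int) -> tuple[tuple[int, ...], ...]:
    """Greedy first-fit packing of whole classes into <= m member batches."""
    batches: list[list[int]] = []
    loads: list[int] = []
    for c, size in enumerate(class_sizes):
        if size > m:
            raise ValueError(
                f"class {c} ({size} particles) exceeds the batch capacity {m}"
            )
        placed = False
        for b, load in enumerate(loads):
            if load + size <= m:
                batches[b].append(c)
                loads[b] += size
                placed = True
                break
        if not placed:
            batches.append([c])
            loads.append(size)
    return tuple(tuple(b) for b in batches)


# ---------------------------------------------------------------------------
# batched executors (equal to the unbatched computation by construction)


def run_multiref_batched(
    particles: np.ndarray,
    references: np.ndarray,
    grid: SearchGrid,
    plan: BatchPlan,
) -> np.ndarray:
    """Execute align_multiref under a BatchPlan; equals the unbatched run.

    Worker subsets and particle batches are looped outermost and reference
    batches innermost, so each particle block is prepared once per pass.
    """
    particles = np.asarray(particles, dtype=float)
    references = np.asarray(references, dtype=float)
    k = references.shape[0]
    out = np.zeros((plan.n, k), dtype=PARAMS_DTYPE)
    for (lo, hi), batches in zip(plan.worker_subsets, plan.particle_batches):
        for a, b in batches:
            block = particles[a:b]
            for ra, rb in plan.reference_batches:
                out[a:b, ra:rb] = align_multiref(block, references[ra:rb], grid)
    return out


def run_assigned_batched(
    particles: np.ndarray,
    assignment: np.ndarray,
    references: np.ndarray,
    grid: SearchGrid,
    plan: BatchPlan,
) -> np.ndarray:
    """Execute align_assigned class-batch-wise; equals the unbatched run."""
    particles = np.asarray(particles, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    out = np.zeros(plan.n, dtype=PARAMS_DTYPE)
    for classes in plan.class_batches:
        sel = np.flatnonzero(np.isin(assignment, classes))
        if sel.size == 0:
            continue
        out[sel] = align_assigned(
            particles[sel], assignment[sel], references, grid
        )
    return out
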