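"""Class-stability testing and the main classification loop.

A class found by equal-size k-means is only trusted if its particles
realign reproducibly: the intra-class alignment is repeated several times
from independently perturbed starting averages, and a particle counts as
stable when the rigid transforms it receives across repetitions agree to
within a pixel-error threshold (RMS displacement on a reference circle,
measured after factoring out each repetition's arbitrary global rotation
of the class average).  The main loop alternates clustering, stability
testing and particle rejection: particles of accepted stable classes are
"accounted for" and removed, everything else is retried, and whatever
never stabilizes is discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import UNASSIGNED, ClassAssignment, ClassConfig, run_kmeans_reps
from .polar_align import (
    PARAMS_DTYPE,
    SearchGrid,
    align,
    average_class,
    iterative_single_ref_align,
    normalize,
    polar_spectra,
)
from .transforms import AlignmentParams, compose_params, pixel_error

DEFAULT_STABILITY_REPS = 5
DEFAULT_STABILITY_ALIGN_ITERS = 30

__all__ = [
    "StabilityConfig",
    "StabilityReport",
    "intra_class_align",
    "pixel_error",
    "stability_test",
    "main_loop",
    "MainLoopResult",
]


@dataclass(frozen=True)
class StabilityConfig:
    """Stability-test configuration.

    Defaults follow standard practice for this algorithm family: the test
    runs 30 alignment iterations of all particles against their class
    average and is itself repeated five times; a particle is stable when
    its mean pairwise pixel error across repetitions is at most
    ``pixel_error_threshold`` pixels, and a class is stable when at least
    ``accounted_fraction_min`` of its members (and no fewer than n_min)
    are stable.
    """

    n_reps: int = DEFAULT_STABILITY_REPS
    n_align_iters: int = DEFAULT_STABILITY_ALIGN_ITERS
    pixel_error_threshold: float = 1.0
    accounted_fraction_min: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.n_align_iters < 1:
            raise ValueError("n_align_iters must be >= 1")
        if self.pixel_error_threshold <= 0 or not 0 < self.accounted_fraction_min <= 1:
            raise ValueError("thresholds must be positive")


@dataclass
class StabilityReport:
    """Per-particle and per-class stability outcome.

    Arrays are indexed like the stack that was tested; particles outside
    any tested class carry pixel_error = inf and stable = False.
    """

    pixel_errors: np.ndarray
    stable_particle: np.ndarray
    class_ids: np.ndarray
    class_stable: np.ndarray
    accounted_counts: np.ndarray
    class_sizes: np.ndarray

    def accounted(self, labels: np.ndarray) -> np.ndarray:
        """Indices of stable particles inside stable classes."""
        ok = np.zeros(len(labels), dtype=bool)
        for c, stable in zip(self.class_ids, self.class_stable):
            if stable:
                ok |= (labels == c) & self.stable_particle
        return np.flatnonzero(ok)


def intra_class_align(
    members: np.ndarray,
    initial_average: np.ndarray,
    grid: SearchGrid,
    n_align_iters: int = DEFAULT_STABILITY_ALIGN_ITERS,
    spectra=None,
):
    """Iteratively align the members of one class to their refined average.

    Structurally the same refinement as the global pre-alignment,
    restricted to one class: every round realigns all members to the
    current average, rebuilds and re-centers it.  Returns (per-member
    params, refined average, mean-peak history).
    """
    members = np.asarray(members, dtype=float)
    if members.shape[0] < 2:
        raise ValueError("intra-class alignment needs at least two members")
    return iterative_single_ref_align(
        members,
        grid,
        n_align_iters,
        initial_reference=initial_average,
        spectra=spectra,
        recenter=True,
    )


def _bootstrap_average(
    images: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Perturbed initial average: bootstrap resample of the members."""
    n = images.shape[0]
    pick = rng.integers(0, n, size=n)
    return normalize(images[pick].mean(axis=0))


def stability_test(
    assignment: ClassAssignment,
    stack,
    grid: SearchGrid,
    cfg: StabilityConfig = StabilityConfig(),
    seed: int = 0,
    spectra=None,
) -> StabilityReport:
    """Score the reproducibility of every class of an assignment.

    Per class: ``cfg.n_reps`` independent intra-class alignments are run
    from bootstrap-perturbed initial averages.  Because each repetition
    may converge to an arbitrarily rotated/shifted version of the average,
    every repetition is first brought into a common gauge by aligning its
    refined average to repetition 0's; the per-particle pixel error is
    then the mean pairwise RMS displacement (on the circle of the
    outermost search ring) between the gauge-corrected transforms.
    """
    images = np.asarray(stack.images, dtype=float)
    n = images.shape[0]
    pixel_errors = np.full(n, np.inf)
    stable_particle = np.zeros(n, dtype=bool)
    class_ids = assignment.active_classes
    class_stable = np.zeros(len(class_ids), dtype=bool)
    accounted_counts = np.zeros(len(class_ids), dtype=np.int64)
    class_sizes = np.zeros(len(class_ids), dtype=np.int64)
    radius = float(grid.max_radius)
    seeds = np.random.SeedSequence(seed).spawn(len(class_ids))

    for ci, c in enumerate(class_ids):
        members = assignment.members(c)
        class_sizes[ci] = members.size
        if members.size < 2:
            continue  # automatically unstable
        sub = images[members]
        class_spectra = (
            spectra.select(members) if spectra is not None else polar_spectra(sub, grid)
        )
        rng = np.random.default_rng(seeds[ci])
        rep_params = []
        rep_avgs = []
        degenerate = False
        for _ in range(cfg.n_reps):
            init = _bootstrap_average(sub, rng)
            try:
                params, avg, _ = intra_class_align(
                    sub, init, grid, cfg.n_align_iters, spectra=class_spectra
                )
            except ValueError:
                degenerate = True
                break
            rep_params.append(params)
            rep_avgs.append(avg)
        if degenerate:
            continue
        errs = _reproducibility_errors(rep_params, rep_avgs, grid, radius)
        pixel_errors[members] = errs
        stable = errs <= cfg.pixel_error_threshold
        stable_particle[members] = stable
        accounted_counts[ci] = int(stable.sum())
        needed = max(
            assignment.n_min,
            math.ceil(cfg.accounted_fraction_min * members.size),
        )
        class_stable[ci] = accounted_counts[ci] >= needed

    return StabilityReport(
        pixel_errors,
        stable_particle,
        class_ids,
        class_stable,
        accounted_counts,
        class_sizes,
    )


def _reproducibility_errors(rep_params, rep_avgs, grid, radius) -> np.ndarray:
    """Mean pairwise pixel error per particle across repetitions.

    Repetition r's transforms are gauge-corrected by G_r, the alignment of
    its refined average onto repetition 0's refined average, before
    comparison.
    """
    n_reps = len(rep_params)
    m = len(rep_params[0])
    corrected: list[list[AlignmentParams]] = []
    for r in range(n_reps):
        gauge = (
            AlignmentParams()
            if r == 0
            else align(rep_avgs[r], rep_avgs[0], grid)
        )
        corrected.append(
            [
                compose_params(gauge, _as_params(rep_params[r][i]))
                for i in range(m)
            ]
        )
    errs = np.zeros(m)
    pairs = [(a, b) for a in range(n_reps) for b in range(a + 1, n_reps)]
    for i in range(m):
        vals = [pixel_error(corrected[a][i], corrected[b][i], radius) for a, b in pairs]
        errs[i] = np.mean(vals)
    return errs


def _as_params(rec) -> AlignmentParams:
    from .polar_align import params_row

    return params_row(rec)


# ---------------------------------------------------------------------------
# main loop


@dataclass
class MainLoopResult:
    """Final outcome of the iterative classify-test-reject loop.

    ``labels[i]`` is the accepted class of particle i in the input stack
    (or UNASSIGNED for discarded particles); ``averages`` holds one image
    per accepted class; ``pixel_errors`` carries the stability metric of
    accepted particles; ``log`` has one dict per main iteration.
    """

    labels: np.ndarray
    averages: list[np.ndarray]
    class_sizes: list[int]
    params: np.ndarray
    pixel_errors: np.ndarray
    log: list[dict] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.averages)

    @property
    def accounted(self) -> np.ndarray:
        return np.flatnonzero(self.labels >= 0)


def main_loop(
    stack,
    grid: SearchGrid,
    class_cfg: ClassConfig,
    stability_cfg: StabilityConfig = StabilityConfig(),
    max_main_iters: int = 10,
    seed: int = 0,
    k: int | None = None,
) -> MainLoopResult:
    """Iterative stable alignment and clustering of a pre-aligned stack.

    Per main iteration: (1) run the seeded k-means repetitions; (2) match
    the partitions one-to-one by maximum class overlap (Hungarian on the
    contingency table); (3) form candidate classes from particles
    co-assigned in a majority of repetitions; (4) stability-test the
    candidates; (5) accept stable classes with at least n_min stable
    members, account their particles and remove them from the working
    stack.  The loop ends when an iteration accepts nothing or
    ``max_main_iters`` is reached; never-accounted particles are
    discarded.
    """
    images = np.asarray(stack.images, dtype=float)
    n = images.shape[0]
    if k is None:
        k = class_cfg.n_classes_target
    n_max, n_min = class_cfg.resolve_sizes(n)
    cfg = ClassConfig(
        n_classes_target=class_cfg.n_classes_target,
        n_max=n_max,
        n_min=n_min,
        k_means_reps=class_cfg.k_means_reps,
        inner_max_iters=class_cfg.inner_max_iters,
        label_change_tol=class_cfg.label_change_tol,
    )
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    final_params = np.zeros(n, dtype=PARAMS_DTYPE)
    pixel_errors = np.full(n, np.inf)
    averages: list[np.ndarray] = []
    class_sizes: list[int] = []
    log: list[dict] = []
    working = np.arange(n)
    seeds = np.random.SeedSequence(seed).spawn(max_main_iters)

    for it in range(max_main_iters):
        if working.size < max(n_min, k):
            break
        sub = images[working]
        it_seed = seeds[it]
        spectra = polar_spectra(sub, grid)
        reps = run_kmeans_reps(
            spectra,
            grid,
            cfg,
            seed=int(it_seed.generate_state(1)[0] % (2**31)),
            k=k,
            images=sub,
        )
        candidates = _consensus_classes(reps, n_min, n_max)
        accepted_here = 0
        entry = {
            "iteration": it,
            "working": int(working.size),
            "candidates": len(candidates),
            "accepted": 0,
            "accounted": 0,
        }
        if candidates:
            cand_assignment = _candidates_to_assignment(
                sub, candidates, reps[0], n_max, n_min
            )
            report = stability_test(
                cand_assignment,
                _SubStack(sub),
                grid,
                stability_cfg,
                seed=int(it_seed.generate_state(2)[1] % (2**31)),
                spectra=spectra,
            )
            for ci, c in enumerate(report.class_ids):
                if not report.class_stable[ci]:
                    continue
                members_local = cand_assignment.members(c)
                stable_local = members_local[report.stable_particle[members_local]]
                if stable_local.size < n_min:
                    continue
                global_ids = working[stable_local]
                cls_index = len(averages)
                labels[global_ids] = cls_index
                pixel_errors[global_ids] = report.pixel_errors[stable_local]
                final_params[global_ids] = cand_assignment.params[stable_local]
                avg, cnt = average_class(
                    sub, cand_assignment.params, member_ids=stable_local
                )
                averages.append(avg)
                class_sizes.append(int(cnt))
                accepted_here += 1
        entry["accepted"] = accepted_here
        entry["accounted"] = int((labels >= 0).sum())
        entry["mean_peak"] = float(
            np.mean([a.peaks.mean() for a in reps])
        )
        log.append(entry)
        working = np.flatnonzero(labels == UNASSIGNED)
        if accepted_here == 0:
            break

    return MainLoopResult(labels, averages, class_sizes, final_params, pixel_errors, log)


class _SubStack:
    """Lightweight image holder with the stack interface used internally."""

    def __init__(self, images: np.ndarray):
        self.images = images
        self.ids = np.arange(images.shape[0])


def _consensus_classes(
    reps: list[ClassAssignment], n_min: int, n_max: int
) -> list[np.ndarray]:
    """Particle sets co-assigned in a majority of matched repetitions.

    Repetitions are relabelled onto repetition 0 by maximum-overlap
    one-to-one matching; a particle belongs to a candidate class when a
    majority (ceil(n_reps / 2)) of repetitions places it there.
    """
    from scipy.optimize import linear_sum_assignment

    n_reps = len(reps)
    k = reps[0].k
    n = len(reps[0].labels)
    votes = np.zeros((n, k), dtype=np.int32)
    base = reps[0].labels
    for r, rep in enumerate(reps):
        lab = rep.labels
        if r > 0:
            overlap = np.zeros((k, k), dtype=np.int64)
            ok = (base >= 0) & (lab >= 0)
            np.add.at(overlap, (lab[ok], base[ok]), 1)
            rows, cols = linear_sum_assignment(-overlap)
            remap = np.full(k, -1, dtype=np.int64)
            remap[rows] = cols
            lab = np.where(lab >= 0, remap[lab], UNASSIGNED)
        for c in range(k):
            votes[:, c] += lab == c
    majority = math.ceil(n_reps / 2)
    out = []
    for c in range(k):
        members = np.flatnonzero(votes[:, c] >= majority)
        if members.size < n_min:
            continue
        if members.size > n_max:
            strength = votes[members, c]
            members = members[np.argsort(-strength, kind="stable")[:n_max]]
            members = np.sort(members)
        out.append(members)
    return out


def _candidates_to_assignment(
    images: np.ndarray,
    candidates: list[np.ndarray],
    base: ClassAssignment,
    n_max: int,
    n_min: int,
) -> ClassAssignment:
    n = images.shape[0]
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    params = np.zeros(n, dtype=PARAMS_DTYPE)
    params[:] = base.params
    avgs = []
    sizes = np.zeros(len(candidates), dtype=np.int64)
    for c, members in enumerate(candidates):
        labels[members] = c
        avg, cnt = average_class(images, base.params, member_ids=members)
        avgs.append(avg)
        sizes[c] = cnt
    return ClassAssignment(
        labels=labels,
        averages=np.stack(avgs),
        sizes=sizes,
        peaks=base.peaks,
        params=params,
        n_max=n_max,
        n_min=n_min,
    )
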