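"""Equal-size k-means over aligned particles.

The clustering inner loop of each main iteration: particles are aligned
against the current class averages (multi-reference alignment), then
re-assigned under a hard per-class capacity so that no class can swallow
the stack.  Assignment is greedy over the globally sorted peak list; an
exact assignment-problem variant is provided as an independent check for
small problems.  Classes that end below the minimum size are dissolved
and their members left unassigned for that repetition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polar_align import (
    PARAMS_DTYPE,
    PolarSpectra,
    SearchGrid,
    align_multiref,
    average_class,
    normalize,
    polar_spectra,
)

UNASSIGNED = -1

DEFAULT_N_CLASSES = 200
DEFAULT_KMEANS_REPS = 5
MIN_MAX_RATIO = 2.0 / 3.0

__all__ = [
    "ClassConfig",
    "ClassAssignment",
    "derive_class_sizes",
    "eq_kmeans",
    "run_kmeans_reps",
    "assign_capacity",
    "assign_capacity_optimal",
    "UNASSIGNED",
]


@dataclass(frozen=True)
class ClassConfig:
    """Equal-size k-means configuration.

    By default the clustering attempts to produce 200 classes, derives the
    maximum class size from the particle count, sets the minimum class
    size to 2/3 of the maximum, and repeats the clustering five times per
    main iteration.
    """

    n_classes_target: int = DEFAULT_N_CLASSES
    n_max: int | None = None
    n_min: int | None = None
    k_means_reps: int = DEFAULT_KMEANS_REPS
    inner_max_iters: int = 20
    label_change_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.n_classes_target < 1:
            raise ValueError("n_classes_target must be >= 1")
        if self.k_means_reps < 1:
            raise ValueError("k_means_reps must be >= 1")
        if self.n_max is not None and self.n_min is not None and self.n_min > self.n_max:
            raise ValueError("n_min must not exceed n_max")

    def resolve_sizes(self, n_particles: int) -> tuple[int, int]:
        if self.n_max is not None:
            n_max = self.n_max
            n_min = self.n_min if self.n_min is not None else math.ceil(MIN_MAX_RATIO * n_max)
            return n_max, n_min
        return derive_class_sizes(n_particles, self)


def derive_class_sizes(n_particles: int, cfg: ClassConfig) -> tuple[int, int]:
    """Maximum and minimum class size from the particle count.

    n_max = ceil(n / target classes); n_min = ceil(2/3 * n_max).
    """
    if n_particles < cfg.n_classes_target:
        raise ValueError(
            f"{n_particles} particles cannot fill {cfg.n_classes_target} classes; "
            "lower n_classes_target"
        )
    n_max = math.ceil(n_particles / cfg.n_classes_target)
    n_min = math.ceil(MIN_MAX_RATIO * n_max)
    return n_max, n_min


@dataclass
class ClassAssignment:
    """A capacity-bounded partition of particles into classes.

    ``labels[i]`` is the class index of particle i or UNASSIGNED (-1).
    ``averages[c]`` and ``sizes[c]`` cover all k classes (dissolved classes
    have size 0); ``params`` holds each particle's alignment to its
    assigned class and ``peaks`` the corresponding correlation peak.
    """

    labels: np.ndarray
    averages: np.ndarray
    sizes: np.ndarray
    peaks: np.ndarray
    params: np.ndarray
    n_max: int
    n_min: int

    @property
    def k(self) -> int:
        return self.averages.shape[0]

    @property
    def active_classes(self) -> np.ndarray:
        return np.flatnonzero(self.sizes > 0)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def validate(self) -> None:
        if (self.sizes > self.n_max).any():
            raise AssertionError("class capacity violated")
        counts = np.bincount(self.labels[self.labels >= 0], minlength=self.k)
        if not np.array_equal(counts, self.sizes):
            raise AssertionError("sizes inconsistent with labels")

    def to_dataframe(self, ids=None) -> pd.DataFrame:
        n = len(self.labels)
        ids = np.arange(n) if ids is None else np.asarray(ids)
        return pd.DataFrame({"id": ids, "class": self.labels, "peak": self.peaks})


# ---------------------------------------------------------------------------
# capacity-constrained assignment


def assign_capacity(
    peaks: np.ndarray, n_max: int, tie_ids: np.ndarray | None = None
) -> np.ndarray:
    """Greedy capacity-constrained assignment from an (n, k) peak matrix.

    Candidate (particle, class) pairs are processed in descending peak
    order; each particle takes its best class that still has room.  Ties
    break by (particle id, class index).  Requires k * n_max >= n.
    """
    n, k = peaks.shape
    if k * n_max < n:
        raise ValueError(f"capacity infeasible: {k} classes x {n_max} < {n} particles")
    ids = np.arange(n) if tie_ids is None else np.asarray(tie_ids)
    flat = peaks.ravel()
    pid = np.repeat(ids, k)
    cid = np.tile(np.arange(k), n)
    order = np.lexsort((cid, pid, -flat))
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    room = np.full(k, n_max, dtype=np.int64)
    row = np.repeat(np.arange(n), k)
    assigned = 0
    for idx in order:
        i = row[idx]
        if labels[i] != UNASSIGNED:
            continue
        j = cid[idx]
        if room[j] > 0:
            labels[i] = j
            room[j] -= 1
            assigned += 1
            if assigned == n:
                break
    return labels


def assign_capacity_optimal(peaks: np.ndarray, n_max: int) -> np.ndarray:
    """Exact peak-sum-maximizing assignment (assignment problem).

    Each class is expanded into n_max unit-capacity slots and solved with
    the Hungarian algorithm.  Intended as an independent cross-check for
    small problems (n * k <= ~1e4), not as the production path.
    """
    from scipy.optimize import linear_sum_assignment

    n, k = peaks.shape
    if k * n_max < n:
        raise ValueError("capacity infeasible")
    cost = np.repeat(-peaks, n_max, axis=1)  # (n, k * n_max)
    rows, cols = linear_sum_assignment(cost)
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    labels[rows] = cols // n_max
    return labels


# ---------------------------------------------------------------------------
# equal-size k-means


def eq_kmeans(
    particles,
    initial_references: np.ndarray,
    grid: SearchGrid,
    cfg: ClassConfig,
    images: np.ndarray | None = None,
) -> ClassAssignment:
    """Equal-size k-means driven by multi-reference alignment peaks.

    Iterates { align to current averages; capacity-constrained greedy
    re-assignment; rebuild averages } until fewer than
    ``cfg.label_change_tol`` of labels change or ``cfg.inner_max_iters``
    is reached.  A re-assignment is only accepted if it does not lower the
    total assigned peak under the current peak matrix.  Classes finishing
    below n_min are dissolved (members left UNASSIGNED).

    ``particles`` may be raw images or a precomputed
    :class:`~isac2d.polar_align.PolarSpectra` (then ``images`` must supply
    the pixel data for averaging).
    """
    if isinstance(particles, PolarSpectra):
        spectra = particles
        if images is None:
            raise ValueError("images are required when passing precomputed spectra")
    else:
        images = np.asarray(particles, dtype=float)
        spectra = polar_spectra(images, grid)
    n = spectra.n
    refs = np.asarray(initial_references, dtype=float)
    if refs.ndim == 2:
        refs = refs[None]
    k = refs.shape[0]
    if n < k:
        raise ValueError("need at least as many particles as classes")
    n_max, n_min = cfg.resolve_sizes(n)
    if k * n_max < n:
        raise ValueError(f"capacity infeasible: {k} x {n_max} < {n}")

    labels = None
    total = -np.inf
    table = None
    for _ in range(cfg.inner_max_iters):
        table = align_multiref(spectra, refs, grid)
        peaks = table["peak"]
        new_labels = assign_capacity(peaks, n_max)
        new_total = float(peaks[np.arange(n), new_labels].sum())
        if labels is not None:
            old_total = float(peaks[np.arange(n), labels].sum())
            if new_total < old_total - 1e-9:
                break  # keep previous assignment; converged
            changed = float(np.mean(new_labels != labels))
        else:
            changed = 1.0
        labels = new_labels
        total = new_total
        refs = _rebuild_averages(images, table, labels, k, refs)
        if changed < cfg.label_change_tol:
            break

    peaks = table["peak"]
    sizes = np.bincount(labels, minlength=k)
    labels = labels.copy()
    for c in range(k):
        if 0 < sizes[c] < n_min:
            labels[labels == c] = UNASSIGNED
    sizes = np.bincount(labels[labels >= 0], minlength=k)
    per_particle = np.zeros(n, dtype=PARAMS_DTYPE)
    best = np.where(labels >= 0, labels, peaks.argmax(axis=1))
    per_particle[:] = table[np.arange(n), best]
    out = ClassAssignment(
        labels=labels,
        averages=refs,
        sizes=sizes,
        peaks=per_particle["peak"],
        params=per_particle,
        n_max=n_max,
        n_min=n_min,
    )
    out.validate()
    return out


def _rebuild_averages(
    images: np.ndarray,
    table: np.ndarray,
    labels: np.ndarray,
    k: int,
    prev_refs: np.ndarray,
) -> np.ndarray:
    refs = np.array(prev_refs, copy=True)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue  # empty class keeps its previous reference
        avg, _ = average_class(images, table[:, c], member_ids=members)
        refs[c] = avg
    return refs


def run_kmeans_reps(
    particles,
    grid: SearchGrid,
    cfg: ClassConfig,
    seed: int,
    k: int | None = None,
    images: np.ndarray | None = None,
) -> list[ClassAssignment]:
    """Run ``cfg.k_means_reps`` independently seeded equal-size k-means.

    Each repetition draws its own random initial references (averages of
    disjoint random particle subsets) from a child seed, so the list is a
    pure function of (particles, grid, cfg, seed).
    """
    if isinstance(particles, PolarSpectra):
        spectra = particles
        if images is None:
            raise ValueError("images are required when passing precomputed spectra")
    else:
        images = np.asarray(particles, dtype=float)
        spectra = polar_spectra(images, grid)
    n = spectra.n
    if k is None:
        k = cfg.n_classes_target
    n_max, _ = cfg.resolve_sizes(n)
    seeds = np.random.SeedSequence(seed).spawn(cfg.k_means_reps)
    out = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        refs = _random_initial_references(images, k, n_max, rng)
        out.append(eq_kmeans(spectra, refs, grid, cfg, images=images))
    return out


def _random_initial_references(
    images: np.ndarray, k: int, n_max: int, rng: np.random.Generator
) -> np.ndarray:
    n = images.shape[0]
    group = max(1, min(n_max, n // k))
    perm = rng.permutation(n)
    refs = np.empty((k,) + images.shape[1:], dtype=float)
    for c in range(k):
        sub = perm[c * group : (c + 1) * group]
        refs[c] = normalize(images[sub].mean(axis=0))
    return refs
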