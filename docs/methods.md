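# Methods

This note documents the model implemented by `isac2d`, the conventions it
fixes, the defaults that matter, what the synthetic generator does and
does not emulate, and the design choices made where the method family
leaves the details open.

## The alignment model

The elementary operation is the alignment function f(p, r): find the rigid
in-plane transform — integer shift (sx, sy) ∈ [s_min, s_max]², rotation θ
on a uniform grid, mirror flag m — that maximizes the similarity of
particle p to reference r.

The search is exhaustive over the discrete grid. For each candidate shift
the particle is resampled onto concentric rings (radii 1..R pixels, by
default R = b/2 − 1 − s_max so every shifted ring stays inside the box)
at n_angular equi-angular points, centered at the box center plus the
shift, with bilinear interpolation. In this polar representation a
rotation of the image is a circular shift along each ring, so the
correlation against the reference over *all* rotations of one candidate is
obtained from one length-n_angular FFT per ring: the ring spectra of
particle and reference are conjugate-multiplied, summed over rings, and
inverse-transformed. The mirrored branch repeats this with the particle
reflected about the vertical axis through the center. A single argmax over
(shift, mirror, rotation) yields the alignment tuple and its peak.

Scores are **normalized** cross-correlations: images are first normalized
to zero mean and unit variance inside a circular mask, rings are weighted
by their circumference (w_r = 2πr, which makes the ring sum approximate
the Cartesian masked inner product), and each polar representation is
scaled to unit weighted norm. A particle correlated with itself therefore
peaks at exactly 1, peaks are comparable across particles (which the
equal-size clustering relies on), and Cauchy–Schwarz guarantees that no
other reference can beat the self-match.

### Conventions (frozen)

* Coordinates: x right, y up, rotation center at array index (b/2, b/2)
  of the even box; positive θ is counter-clockwise.
* `AlignmentParams(sx, sy, theta, mirror)` encodes the *registration*
  transform T = R_θ ∘ S_(sx,sy) ∘ M^m: mirror first, then translate by
  (sx, sy), then rotate. `apply_transform(p, params)` applies T to the
  particle and brings it into register with the reference.
* This order matches the search's construction — the search shifts the
  sampling center and then rotates in polar space — so the shifts stored
  in alignment tuples lie exactly on the integer search grid, and
  ground-truth integer shifts are recovered *exactly* rather than up to a
  rotated fraction of a pixel. The alternative order (rotate before
  shift) would store each grid shift rotated by θ, off the integer grid.
  Composition and inversion of transforms go through their 2×2 affine
  form (`compose_params`, `invert_params`); inverses and compositions are
  generally off-grid, which is fine — `apply_transform` accepts real-
  valued shifts.
* n_angular defaults to the smallest power of two ≥ 2πR, i.e. at most
  about one pixel of arc between samples on the outermost ring.
* Ties in the argmax break to the lowest flat index in shift-major, then
  mirror, then rotation order; all batch operations are pure functions of
  their inputs, so batched, chunked and worker-split executions are
  identical to the unbatched computation.

### Gauge freedom

Reference-free refinement (pre-alignment, intra-class alignment) defines
its solution only up to a global rotation — and, when the mirrored search
is enabled, a global mirror — of the converged average. Recovered
parameters are therefore only comparable to ground truth after fixing
that gauge: tests either restrict the search to the generator's transform
group, or compare through the alignment of the refined average to the
known motif. The stability metric (below) factors the same gauge out
explicitly.

## Pipeline stages and defaults

* **Pre-alignment** (`prealign`): every particle is aligned to the
  current global average (a k = 1 alignment with a correspondingly small
  cross-correlation table), the average is rebuilt from the transformed
  particles, normalized, and re-centered on the masked center of mass of
  its positive part (this prevents slow drift of the solution). The
  initial reference is the average of the normalized raw particles.
  Default: 14 iterations, no early stopping. A translation-only mode
  exists for speed; the full search is the default.
* **Class sizes**: the clustering targets 200 classes by default and
  derives n_max = ⌈n / 200⌉ from the stack, with n_min = ⌈2/3 · n_max⌉.
* **Equal-size k-means** (`eq_kmeans`): each inner iteration aligns all
  particles against all current class averages, then re-assigns particles
  greedily in descending peak order, each particle taking its best class
  with remaining capacity (ties by particle id, then class index). A
  re-assignment is only accepted if it does not lower the total assigned
  peak under the current peak matrix. The inner loop stops when fewer
  than 1% of labels change or after 20 iterations. Classes ending below
  n_min are dissolved. The greedy assignment costs O(nk log nk); an exact
  Hungarian variant over n_max-expanded class slots is included as an
  independent cross-check for small problems and agrees with the greedy
  rule whenever classes are well separated. Initial references are
  averages of disjoint random particle subsets. Five independently seeded
  repetitions run per main iteration.
* **Stability test** (`stability_test`): per class, five repetitions of
  30 intra-class alignment iterations, each repetition starting from a
  bootstrap-resampled average so that reproducibility is informative.
  Repetition r is brought into the gauge of repetition 0 by aligning its
  refined average to repetition 0's. The per-particle **pixel error** is
  the mean pairwise RMS displacement, over points on the circle of the
  outermost search ring, between the gauge-corrected transforms of the
  repetitions; a mirror disagreement counts as infinite. A particle is
  stable at pixel error ≤ 1.0 px (configurable); a class is stable when
  at least max(n_min, 2/3 of its members) are stable.
* **Main loop** (`main_loop`): the five k-means partitions are matched
  one-to-one by maximum overlap (Hungarian on the contingency table);
  candidate classes are the particle sets co-assigned in at least
  ⌈5/2⌉ = 3 partitions (truncated to n_max by co-assignment strength if
  needed, dropped if below n_min). Candidates are stability-tested;
  accepted classes keep their stable members, which become *accounted*
  and leave the working stack. The loop ends when an iteration accepts
  nothing, or after 10 iterations; remaining particles are discarded.
  Every emitted class has between n_min and n_max members, and the
  accounted set grows monotonically. The whole pipeline is a
  deterministic function of (stack, configuration, seed); all randomness
  flows through seeded generators spawned from one root seed.
* **Scheduler** (`plan_batches`): the memory model counts, per batch of m
  particles against k references — input images m·b², particle polar
  spectra m·S·M·R·(A/2+1) complex values (S shifts, M mirror branches),
  reference spectra k·R·(A/2+1) complex, the cross-correlation table
  m·k·S·M·A, and m·k 5-field output tuples — at 8 bytes per element. The
  planner picks the largest m (and if necessary the largest reference
  sub-batch) whose estimate fits memory_fraction (default 0.95) of the
  budget (default 2 GiB), splits the stack into contiguous near-equal
  worker subsets, and orders multi-reference work particle-batch-outer /
  reference-batch-inner so each particle is prepared once per pass; the
  assigned/stability stage packs whole classes per batch instead. The
  mirror factor M is included in the spectra term because the search
  stores both branches.

## The synthetic generator

`make_synthetic_stack` emulates the standard test regime for 2D
classification methods: stacks of known 2D motifs under random in-plane
rotation (uniform in [0, 360)), integer shifts (uniform in
[−max_shift, max_shift]²), optional mirroring (probability 1/2), and
additive white Gaussian noise. The SNR is defined as signal variance over
noise variance inside the circular mask of radius b/2 − 2, calibrated per
particle; snr = ∞ disables noise and snr = 0 produces pure-noise images.
Shifts are integer-valued so that recovery against the integer search
grid can be scored exactly. The stack is a pure function of its
arguments, including the seed.

The eight built-in motifs are irregular Gaussian-blob constellations,
centered on their mixture centroid and contained within 0.62 of the
half-box. They were screened so that no rotation by 20° or more, no
mirrored rotation, and no cross-motif comparison exceeds a normalized
correlation of about 0.8 — the test suite audits a 0.9 bound — making
recovered rotations, mirror flags and class labels unambiguous.

What the generator does **not** emulate: contrast transfer functions and
defocus variation, structured/colored noise, particle heterogeneity
within a class (conformations, partial occupancy), neighboring-particle
density, and non-integer true shifts. Passing tests therefore demonstrate
the correctness of the search, the clustering contract and the
reject-unstable logic under the stated noise model — not performance on
real micrograph-derived data, where CTF handling (out of scope here)
would be required first.

## Numerical choices and limitations

* Bilinear interpolation everywhere (polar sampling and image
  transforms); test tolerance budgets account for it. Rotating an image
  and sampling its rings is *exactly* equivalent to circularly shifting
  sampled rings only on the rotation grid, which is why the discrete
  search is exact while sub-grid rotations incur interpolation error.
* float64/complex128 throughout; batched and looped paths agree to
  ~1e-9 relative (tested at 1e-6).
* Degenerate (zero-contrast) images are flagged, score 0 and carry the
  identity transform; all-degenerate inputs are an error.
* The polar representation discards radii below 1 px and the DC pixel;
  information within the innermost pixel does not contribute.
* No sub-pixel shift or sub-increment rotation refinement is attempted;
  the resolution of the recovered parameters is one grid step.
* Desk-scale problem sizes are used in tests and in
  `scripts/acceptance.py` (e.g. four motifs × 300 particles at box 32,
  500-particle null stacks, kernels timed up to n = 4000 at box 24);
  the algorithmic path exercised is the same one the scheduler streams
  at arbitrary n.
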