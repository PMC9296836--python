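"""Polar/FFT 2D alignment kernels.

The exhaustive alignment search evaluates, for every candidate integer
shift, mirror flag and rotation on a discrete grid, the normalized
cross-correlation between a particle and a reference.  Images are
resampled onto concentric rings (polar representation) around the shifted
center, so that rotation becomes a circular shift per ring and the
correlation over all rotations of one (shift, mirror) candidate is computed
with a single 1D FFT per ring.

Scores are ring-weighted normalized cross-correlations in [-1, 1]: rings
are weighted by their circumference (w_r = 2 pi r), and each polar
representation is scaled to unit weighted norm, so a particle correlated
with itself peaks at exactly 1 and peaks are comparable across particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .transforms import AlignmentParams, mirror_image

__all__ = [
    "SearchGrid",
    "PolarSpectrum",
    "PolarSpectra",
    "normalize",
    "to_polar_fft",
    "ccf_rotational",
    "align",
    "align_multiref",
    "align_assigned",
    "average_class",
    "iterative_single_ref_align",
]


def _next_pow2(x: int) -> int:
    n = 4
    while n < x:
        n *= 2
    return n


@dataclass(frozen=True)
class SearchGrid:
    """The discrete alignment search space.

    ``shifts`` enumerates all integer (sx, sy) in
    [s_min, s_max] x [s_min, s_max] on the step grid; rotations are the
    n_angular multiples of 360 / n_angular degrees; ``mirror`` toggles the
    mirrored branch.  Every shifted ring must stay inside the box:
    max(ring_radii) + max(|s_min|, s_max) < b / 2.
    """

    s_min: int = -3
    s_max: int = 3
    shift_step: int = 1
    ring_radii: tuple[int, ...] = ()
    n_angular: int = 64
    mirror: bool = True

    def __post_init__(self) -> None:
        if not (self.s_min <= 0 <= self.s_max):
            raise ValueError("require s_min <= 0 <= s_max")
        if self.shift_step < 1:
            raise ValueError("shift_step must be >= 1")
        if not self.ring_radii:
            raise ValueError("ring_radii must be non-empty")
        if any(r < 1 for r in self.ring_radii):
            raise ValueError("ring radii must be >= 1")
        if self.n_angular < 4 or self.n_angular % 2:
            raise ValueError("n_angular must be even and >= 4")

    @classmethod
    def for_box(
        cls,
        box: int,
        s_max: int = 3,
        s_min: int | None = None,
        shift_step: int = 1,
        max_ring: int | None = None,
        n_angular: int | None = None,
        mirror: bool = True,
    ) -> "SearchGrid":
        """Default grid for a given box size.

        Rings run from 1 to b/2 - 1 - s_max so every shifted ring stays in
        frame; n_angular defaults to the smallest power of two covering one
        sample per pixel of arc on the outermost ring (>= 2 pi R).
        """
        if s_min is None:
            s_min = -s_max
        r_max = max_ring if max_ring is not None else box // 2 - 1 - max(abs(s_min), s_max)
        if r_max < 1:
            raise ValueError("box too small for the requested shift range")
        radii = tuple(range(1, r_max + 1))
        if n_angular is None:
            n_angular = _next_pow2(int(math.ceil(2 * math.pi * r_max)))
        return cls(s_min, s_max, shift_step, radii, n_angular, mirror)

    @property
    def shifts(self) -> tuple[tuple[int, int], ...]:
        rng = range(self.s_min, self.s_max + 1, self.shift_step)
        return tuple((sx, sy) for sx in rng for sy in rng)

    @property
    def n_shifts(self) -> int:
        return len(self.shifts)

    @property
    def n_mirror(self) -> int:
        return 2 if self.mirror else 1

    @property
    def angular_increment(self) -> float:
        return 360.0 / self.n_angular

    @property
    def max_radius(self) -> int:
        return max(self.ring_radii)

    def validate_box(self, box: int) -> None:
        if self.max_radius + max(abs(self.s_min), self.s_max) >= box // 2:
            raise ValueError(
                f"grid (R={self.max_radius}, s_max={self.s_max}) does not fit "
                f"inside box {box}: shifted rings would leave the frame"
            )

    @property
    def ring_weights(self) -> np.ndarray:
        """Circumference weights w_r = 2 pi r."""
        return 2.0 * np.pi * np.asarray(self.ring_radii, dtype=float)


# ---------------------------------------------------------------------------
# sampling machinery


class _Sampler:
    """Precomputed bilinear gather for polar resampling of a given box.

    The resampling is a fixed linear map from pixel space to the
    (shift, ring, angle) sample grid; it is stored as one sparse matrix
    with four weights per sample point so a whole image batch resamples
    with a single sparse-dense product.
    """

    def __init__(self, grid: SearchGrid, box: int):
        import scipy.sparse as sparse

        grid.validate_box(box)
        self.grid = grid
        self.box = box
        c = box // 2
        radii = np.asarray(grid.ring_radii, dtype=float)
        phi = 2.0 * np.pi * np.arange(grid.n_angular) / grid.n_angular
        # ring point offsets in math frame (x right, y up)
        x = radii[:, None] * np.cos(phi)[None, :]
        y = radii[:, None] * np.sin(phi)[None, :]
        shifts = np.asarray(grid.shifts, dtype=float)  # (S, 2)
        rows = (c - y)[None] - shifts[:, 1, None, None]  # row = c - (y + sy)
        cols = (c + x)[None] + shifts[:, 0, None, None]
        r0 = np.floor(rows).astype(np.int64)
        c0 = np.floor(cols).astype(np.int64)
        fr = rows - r0
        fc = cols - c0
        self.shape = rows.shape  # (S, R, A)
        n_pts = rows.size
        # zero-weight +1 neighbors of points landing exactly on a lattice
        # row/col may index one past the edge; clip (their weight is 0)
        idx = [
            (np.clip(r0 + dr, 0, box - 1) * box + np.clip(c0 + dc, 0, box - 1)).ravel()
            for dr in (0, 1)
            for dc in (0, 1)
        ]
        # ring-circumference weights are folded into the sampling matrix
        # (each sample row is scaled by sqrt(2 pi r) of its ring)
        sqrt_w = np.broadcast_to(
            np.sqrt(grid.ring_weights)[None, :, None], self.shape
        ).ravel()
        w = [
            ((fr if dr else 1 - fr) * (fc if dc else 1 - fc)).ravel() * sqrt_w
            for dr in (0, 1)
            for dc in (0, 1)
        ]
        self.matrix = sparse.csr_matrix(
            (
                np.concatenate(w),
                (np.tile(np.arange(n_pts), 4), np.concatenate(idx)),
            ),
            shape=(n_pts, box * box),
        )

    def sample(self, images: np.ndarray) -> np.ndarray:
        """images (m, b, b) -> weighted polar samples (m, S, R, A)."""
        m = images.shape[0]
        flat_t = np.ascontiguousarray(images.reshape(m, -1).T)
        return (self.matrix @ flat_t).T.reshape((m,) + self.shape)

    def sample_into(self, images: np.ndarray, out: np.ndarray) -> None:
        """Resample into a preallocated (m, S, R, A) destination view."""
        m = images.shape[0]
        flat_t = np.ascontiguousarray(images.reshape(m, -1).T)
        res = self.matrix @ flat_t  # (S*R*A, m)
        out[...] = res.reshape(self.shape + (m,)).transpose(3, 0, 1, 2)


_SAMPLER_CACHE: dict[tuple, _Sampler] = {}


def _sampler(grid: SearchGrid, box: int) -> _Sampler:
    key = (grid, box)
    s = _SAMPLER_CACHE.get(key)
    if s is None:
        s = _SAMPLER_CACHE[key] = _Sampler(grid, box)
    return s


# ---------------------------------------------------------------------------
# normalization


def normalize(
    image: np.ndarray,
    mask_radius: float | None = None,
    return_flag: bool = False,
):
    """Zero-mean, unit-variance normalization inside a circular mask.

    The masked mean is subtracted everywhere; pixels inside the mask are
    additionally scaled to unit variance.  A constant image has no scale
    and is returned as all zeros with the degenerate flag set.
    """
    img = np.asarray(image, dtype=float)
    b = img.shape[-1]
    if mask_radius is None:
        mask_radius = b / 2 - 1
    mask = _circular_mask(b, mask_radius)
    vals = img[..., mask]
    mu = vals.mean(axis=-1)
    sd = vals.std(axis=-1)
    out = img - (mu[..., None, None] if img.ndim == 3 else mu)
    degenerate = sd < 1e-12
    if img.ndim == 2:
        if degenerate:
            out = np.zeros_like(out)
        else:
            out[mask] /= sd
    else:
        safe = np.where(degenerate, 1.0, sd)
        out[:, mask] /= safe[:, None]
        out[degenerate] = 0.0
    if return_flag:
        return out, degenerate
    return out


def _circular_mask(box: int, radius: float) -> np.ndarray:
    c = box // 2
    jj, ii = np.meshgrid(np.arange(box), np.arange(box))
    return (jj - c) ** 2 + (ii - c) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# polar spectra


@dataclass(frozen=True)
class PolarSpectrum:
    """Ring-wise rFFT of one polar-resampled, shifted, normalized image."""

    data: np.ndarray  # (R, n_angular // 2 + 1) complex
    grid: SearchGrid
    box: int

    def rings(self) -> np.ndarray:
        """Inverse-FFT back to the (weighted) polar ring samples."""
        return np.fft.irfft(self.data, n=self.grid.n_angular, axis=-1)


@dataclass(frozen=True)
class PolarSpectra:
    """Batch of per-(particle, shift, mirror) ring spectra.

    Conceptually an (m, S, M, R, F) complex array with F = n_angular//2+1;
    each (particle, shift, mirror) polar representation is scaled to unit
    weighted norm and ``degenerate`` flags particles with no contrast.
    Physically the conjugated spectra are stored in the correlation
    engine's layout, shape (F, m*S*M, R), so the per-frequency matmul
    against reference spectra runs without any large transpose copy.
    """

    engine: np.ndarray  # (F, m * S * M, R) complex, conjugated
    grid: SearchGrid
    box: int
    n: int
    degenerate: np.ndarray = field(default=None)  # (m,) bool

    @property
    def _block(self) -> int:
        return self.grid.n_shifts * self.grid.n_mirror

    def slice(self, lo: int, hi: int) -> "PolarSpectra":
        """Contiguous particle range as a view (no copy)."""
        blk = self._block
        return PolarSpectra(
            self.engine[:, lo * blk : hi * blk],
            self.grid,
            self.box,
            hi - lo,
            None if self.degenerate is None else self.degenerate[lo:hi],
        )

    def select(self, indices: np.ndarray) -> "PolarSpectra":
        """Arbitrary particle subset (copies the selected rows)."""
        idx = np.asarray(indices, dtype=int)
        blk = self._block
        rows = (idx[:, None] * blk + np.arange(blk)).ravel()
        return PolarSpectra(
            self.engine[:, rows],
            self.grid,
            self.box,
            idx.size,
            None if self.degenerate is None else self.degenerate[idx],
        )


def _polar_batch(
    images: np.ndarray,
    grid: SearchGrid,
    mirror: bool,
    normalize_images: bool = True,
) -> PolarSpectra:
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    box = images.shape[-1]
    if normalize_images:
        images, degen = normalize(images, return_flag=True)
    else:
        degen = np.zeros(images.shape[0], dtype=bool)
    smp = _sampler(grid, box)
    m = images.shape[0]
    S, R, A = smp.shape
    n_mirror = 2 if mirror else 1
    polar = np.empty((m, S, n_mirror, R, A))
    smp.sample_into(images, polar[:, :, 0])
    if mirror:
        smp.sample_into(mirror_image(images), polar[:, :, 1])
    norms = np.sqrt(np.einsum("msbra,msbra->msb", polar, polar))
    norms[norms < 1e-12] = 1.0
    polar /= norms[..., None, None]
    spec = np.fft.rfft(polar, axis=-1)  # (m, S, M, R, F)
    np.negative(spec.imag, out=spec.imag)  # conjugate in place
    m = images.shape[0]
    s, mm, r, f = spec.shape[1:]
    engine = np.ascontiguousarray(
        spec.reshape(m * s * mm, r, f).transpose(2, 0, 1)
    )
    return PolarSpectra(engine, grid, box, m, degen)


def _ref_polar(references: np.ndarray, grid: SearchGrid) -> np.ndarray:
    """Reference ring spectra at zero shift, unmirrored: (k, R, F) complex."""
    refs = np.asarray(references, dtype=float)
    if refs.ndim == 2:
        refs = refs[None]
    refs, _ = normalize(refs, return_flag=True)
    smp = _sampler(grid, refs.shape[-1])
    zero = grid.shifts.index((0, 0))
    polar = smp.sample(refs)[:, zero]  # (k, R, A)
    norms = np.sqrt(np.sum(polar**2, axis=(-2, -1), keepdims=True))
    norms[norms < 1e-12] = 1.0
    polar = polar / norms
    return np.fft.rfft(polar, axis=-1)


def to_polar_fft(
    image: np.ndarray,
    grid: SearchGrid,
    shift: tuple[int, int] = (0, 0),
    unit_norm: bool = True,
) -> PolarSpectrum:
    """Polar-resample one image around center + shift and rFFT each ring.

    Ring r is sampled at n_angular equi-angular points on the circle of
    radius r centered at (b/2 + sx, b/2 + sy), bilinear interpolation,
    weighted by sqrt(2 pi r); by default the ring stack is scaled to unit
    weighted norm.
    """
    if tuple(shift) not in grid.shifts:
        raise ValueError(f"shift {shift} is not on the search grid")
    img = np.asarray(image, dtype=float)
    smp = _sampler(grid, img.shape[-1])
    s_idx = grid.shifts.index(tuple(shift))
    polar = smp.sample(img[None])[0, s_idx]  # (R, A)
    if unit_norm:
        nrm = float(np.sqrt(np.sum(polar**2)))
        if nrm > 1e-12:
            polar = polar / nrm
    return PolarSpectrum(np.fft.rfft(polar, axis=-1), grid, img.shape[-1])


def ccf_rotational(p: PolarSpectrum, r: PolarSpectrum) -> np.ndarray:
    """Cross-correlation over rotation angle, via ring-wise FFT products.

    Entry ``a`` is the correlation of the particle rotated counter-clockwise
    by ``a * 360 / n_angular`` degrees with the reference, summed over rings
    (ring weights are already folded into the spectra).
    """
    if p.grid != r.grid or p.box != r.box:
        raise ValueError("polar spectra were built on different grids")
    prod = np.conj(p.data) * r.data
    return np.fft.irfft(prod.sum(axis=0), n=p.grid.n_angular)


# ---------------------------------------------------------------------------
# CCF engine and searches


def _ccf_tables(pspec: PolarSpectra, ref: np.ndarray) -> np.ndarray:
    """Full cross-correlation table, shape (m, k, S, M, A).

    Row (i, j) holds the correlation of particle i with reference j for
    every shift, mirror branch and rotation on the grid.  ``ref`` holds
    the reference ring spectra (k, R, F) at zero shift, unmirrored.
    """
    grid = pspec.grid
    m = pspec.n
    S, M = grid.n_shifts, grid.n_mirror
    k = ref.shape[0]
    # per-frequency batched matmul: (F, m*S*M, R) @ (F, R, k) -> (F, m*S*M, k)
    y = ref.transpose(2, 1, 0)
    z = np.matmul(pspec.engine, y)  # (F, mSM, k)
    z = z.transpose(1, 2, 0)  # (mSM, k, F)
    ccf = np.fft.irfft(z, n=grid.n_angular, axis=-1)
    ccf = ccf.reshape(m, S, M, k, grid.n_angular).transpose(0, 3, 1, 2, 4)
    return np.ascontiguousarray(ccf)


def _extract_params(
    ccf: np.ndarray, grid: SearchGrid, degenerate: np.ndarray | None
) -> np.ndarray:
    """Argmax over (shift, mirror, rotation) per (particle, reference).

    Ties break to the lowest flat index in shift-major, then mirror, then
    rotation order.  Returns a structured array (m, k) with fields
    sx, sy, theta, mirror, peak, degenerate.
    """
    m, k = ccf.shape[:2]
    flat = ccf.reshape(m, k, -1)
    best = np.argmax(flat, axis=-1)
    peaks = np.take_along_axis(flat, best[..., None], axis=-1)[..., 0]
    S, M, A = ccf.shape[2:]
    s_idx, m_idx, a_idx = np.unravel_index(best, (S, M, A))
    shifts = np.asarray(grid.shifts)
    out = np.zeros((m, k), dtype=PARAMS_DTYPE)
    # registration shift is minus the sampling-center shift
    out["sx"] = -shifts[s_idx, 0]
    out["sy"] = -shifts[s_idx, 1]
    out["theta"] = (a_idx * grid.angular_increment) % 360.0
    out["mirror"] = m_idx
    out["peak"] = peaks
    if degenerate is not None and degenerate.any():
        for name in ("sx", "sy", "theta", "mirror"):
            out[name][degenerate] = 0
        out["peak"][degenerate] = 0.0
        out["degenerate"][degenerate] = True
    return out


PARAMS_DTYPE = np.dtype(
    [
        ("sx", "f8"),
        ("sy", "f8"),
        ("theta", "f8"),
        ("mirror", "i4"),
        ("peak", "f8"),
        ("degenerate", "?"),
    ]
)


def params_row(rec) -> AlignmentParams:
    """Convert one structured-array record to an AlignmentParams."""
    return AlignmentParams(
        float(rec["sx"]),
        float(rec["sy"]),
        float(rec["theta"]),
        int(rec["mirror"]),
        peak=float(rec["peak"]),
        degenerate=bool(rec["degenerate"]),
    )


def _as_spectra(particles, grid: SearchGrid) -> PolarSpectra:
    if isinstance(particles, PolarSpectra):
        if particles.grid != grid:
            raise ValueError("precomputed spectra use a different grid")
        return particles
    return _polar_batch(np.asarray(particles, dtype=float), grid, grid.mirror)


def align_multiref(
    particles,
    references,
    grid: SearchGrid,
    chunk: int | None = None,
) -> np.ndarray:
    """Align every particle against every reference.

    Returns a structured array of shape (m, k): entry (i, j) is the
    exhaustive-search optimum of particle i against reference j, identical
    to ``align(p_i, r_j)``.  ``out['peak']`` is the m x k peak matrix used
    for best / second-best reference ranking.  ``particles`` may be a
    (m, b, b) array or a precomputed :class:`PolarSpectra`.  ``chunk``
    bounds the number of particles processed per block.
    """
    pspec = _as_spectra(particles, grid)
    refs = np.asarray(references, dtype=float)
    if refs.ndim == 2:
        refs = refs[None]
    m = pspec.n
    if m == 0 or refs.shape[0] == 0:
        raise ValueError("need at least one particle and one reference")
    if pspec.box != refs.shape[-1]:
        raise ValueError("particles and references have different box sizes")
    ref = _ref_polar(refs, grid)
    step = chunk or m
    blocks = []
    for lo in range(0, m, step):
        sub = pspec.slice(lo, min(lo + step, m))
        ccf = _ccf_tables(sub, ref)
        blocks.append(_extract_params(ccf, grid, sub.degenerate))
    return np.concatenate(blocks, axis=0) if len(blocks) > 1 else blocks[0]


def align(particle: np.ndarray, reference: np.ndarray, grid: SearchGrid) -> AlignmentParams:
    """Exhaustive (shift, mirror, rotation) alignment of one pair.

    Applying the returned parameters with ``apply_transform`` brings the
    particle into register with the reference; the peak is the normalized
    cross-correlation at the optimum.
    """
    table = align_multiref(np.asarray(particle)[None], np.asarray(reference)[None], grid)
    return params_row(table[0, 0])


def align_assigned(
    particles,
    assignment: Sequence[int] | np.ndarray,
    references,
    grid: SearchGrid,
    chunk: int | None = None,
) -> np.ndarray:
    """Align each particle to its single pre-assigned reference.

    Returns a structured array of shape (m,); result i equals
    ``align(p_i, r_assignment[i])``.  The cross-correlation table is built
    per reference group, so storage is independent of the number of
    references.
    """
    pspec = _as_spectra(particles, grid)
    refs = np.asarray(references, dtype=float)
    if refs.ndim == 2:
        refs = refs[None]
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape[0] != pspec.n:
        raise ValueError("assignment length must match the particle count")
    if assignment.min() < 0 or assignment.max() >= refs.shape[0]:
        raise ValueError("assignment indexes a non-existent reference")
    out = np.zeros(pspec.n, dtype=PARAMS_DTYPE)
    for j in np.unique(assignment):
        sel = np.flatnonzero(assignment == j)
        sub = pspec.select(sel)
        out[sel] = align_multiref(sub, refs[j][None], grid, chunk=chunk)[:, 0]
    return out


# ---------------------------------------------------------------------------
# averaging and iterative single-reference alignment


def average_class(
    particles: np.ndarray,
    params,
    member_ids: Sequence[int] | None = None,
    mask_radius: float | None = None,
) -> tuple[np.ndarray, int]:
    """Pixel-wise mean of transformed members, normalized; returns count."""
    from .transforms import apply_transforms_batch

    imgs = np.asarray(particles, dtype=float)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if member_ids is not None:
        idx = np.asarray(member_ids, dtype=int)
        imgs = imgs[idx]
        params = params[idx] if isinstance(params, np.ndarray) else [params[i] for i in idx]
    n = imgs.shape[0]
    if n == 0:
        raise ValueError("average_class requires at least one member")
    acc = apply_transforms_batch(imgs, params).mean(axis=0)
    return normalize(acc, mask_radius), n


def _recenter(image: np.ndarray, mask_radius: float | None = None) -> np.ndarray:
    """Shift an average so its masked center of mass sits at the center."""
    from .transforms import apply_transform

    b = image.shape[-1]
    if mask_radius is None:
        mask_radius = b / 2 - 1
    mask = _circular_mask(b, mask_radius)
    w = np.clip(image, 0.0, None) * mask
    tot = w.sum()
    if tot <= 1e-12:
        return image
    c = b // 2
    jj, ii = np.meshgrid(np.arange(b), np.arange(b))
    com_x = float((w * (jj - c)).sum() / tot)
    com_y = float((w * (c - ii)).sum() / tot)
    if abs(com_x) < 1e-3 and abs(com_y) < 1e-3:
        return image
    return apply_transform(image, AlignmentParams(-com_x, -com_y, 0.0, 0))


def iterative_single_ref_align(
    images: np.ndarray,
    grid: SearchGrid,
    n_iters: int,
    initial_reference: np.ndarray | None = None,
    spectra: PolarSpectra | None = None,
    recenter: bool = True,
    rotation: bool = True,
):
    """Repeatedly align a set of images to one refined common reference.

    Each round aligns every image to the current reference (k = 1, reduced
    cross-correlation table), rebuilds the reference as the transformed
    average, and re-centers it.  The particle polar spectra are computed
    once and reused across rounds.  Returns (params, reference,
    mean_peak_history).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if spectra is None:
        spectra = _polar_batch(images, grid, grid.mirror)
    if spectra.degenerate is not None and spectra.degenerate.all():
        raise ValueError("all images are degenerate (zero contrast)")
    if initial_reference is None:
        reference = normalize(images.mean(axis=0))
    else:
        reference = normalize(np.asarray(initial_reference, dtype=float))
    params = None
    history = []
    for _ in range(int(n_iters)):
        if rotation:
            params = align_multiref(spectra, reference[None], grid)[:, 0]
        else:
            params = _restrict_rotation(spectra, reference, grid)
        history.append(float(params["peak"].mean()))
        reference, _ = average_class(images, params)
        if recenter:
            reference = normalize(_recenter(reference))
    return params, reference, history


def _restrict_rotation(spectra: PolarSpectra, reference: np.ndarray, grid: SearchGrid):
    """Shift-only search: rotation fixed to 0, mirror fixed to 0."""
    ref = _ref_polar(reference[None], grid)
    ccf = _ccf_tables(spectra, ref)  # (m, 1, S, M, A)
    ccf = ccf[:, :, :, :1, :1]
    return _extract_params(ccf, grid, spectra.degenerate)[:, 0]


def polar_spectra(images: np.ndarray, grid: SearchGrid) -> PolarSpectra:
    """Precompute the per-(shift, mirror) polar spectra of an image batch."""
    return _polar_batch(np.asarray(images, dtype=float), grid, grid.mirror)
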