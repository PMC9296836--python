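"""Rigid in-plane transforms: alignment parameters, composition, resampling.

Conventions (frozen; everything in the package agrees with these):

* Math frame: ``x = col - b/2`` (right), ``y = b/2 - row`` (up); the rotation
  center is the pixel at array index ``(b/2, b/2)`` of an even ``b`` box.
* ``AlignmentParams(sx, sy, theta, mirror)`` encodes the registration
  transform ``T = R_theta ∘ S_(sx,sy) ∘ M^mirror`` — mirror the particle
  about the vertical axis, translate its content by ``(sx, sy)`` pixels,
  then rotate counter-clockwise by ``theta`` degrees.  This order matches
  the exhaustive search (shift the sampling center, rotate in polar space),
  so the shifts returned by the aligner live exactly on the integer search
  grid.
* ``apply_transform(image, params)`` resamples so the output is ``T``
  applied to the image content; applying the params returned by the aligner
  brings a particle into register with its reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AlignmentParams",
    "apply_transform",
    "compose_params",
    "invert_params",
    "params_to_affine",
    "affine_to_params",
    "mirror_image",
    "pixel_error",
]

_MIRROR = np.array([[-1.0, 0.0], [0.0, 1.0]])


@dataclass(frozen=True)
class AlignmentParams:
    """One alignment parameter tuple (sx, sy, theta, mirror) with its peak.

    ``sx``/``sy`` are pixels, ``theta`` degrees in [0, 360), ``mirror`` 0/1.
    ``peak`` is the normalized cross-correlation value at the optimum and
    ``degenerate`` flags an all-constant input for which no alignment is
    defined (identity transform, peak 0).
    """

    sx: float = 0.0
    sy: float = 0.0
    theta: float = 0.0
    mirror: int = 0
    peak: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mirror not in (0, 1):
            raise ValueError(f"mirror must be 0 or 1, got {self.mirror}")
        object.__setattr__(self, "theta", float(self.theta) % 360.0)

    @property
    def identity(self) -> bool:
        return self.sx == 0 and self.sy == 0 and self.theta == 0 and self.mirror == 0


def _rot(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def params_to_affine(p: AlignmentParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (L, t) with ``T(v) = L v + t`` in the math frame."""
    r = _rot(p.theta)
    lin = r @ _MIRROR if p.mirror else r
    shift = r @ np.array([p.sx, p.sy], dtype=float)
    return lin, shift


def affine_to_params(lin: np.ndarray, t: np.ndarray, peak: float = 0.0) -> AlignmentParams:
    """Decompose an orthogonal affine back into (sx, sy, theta, mirror).

    Shifts of a composed or inverted transform are generally not on the
    integer search grid.
    """
    mirror = 1 if np.linalg.det(lin) < 0 else 0
    rot = lin @ _MIRROR if mirror else lin
    theta = math.degrees(math.atan2(rot[1, 0], rot[0, 0])) % 360.0
    shift = rot.T @ t  # R^{-1} t
    return AlignmentParams(float(shift[0]), float(shift[1]), theta, mirror, peak=peak)


def compose_params(a: AlignmentParams, b: AlignmentParams) -> AlignmentParams:
    """Parameters of ``T_a ∘ T_b`` (apply ``b`` first)."""
    la, ta = params_to_affine(a)
    lb, tb = params_to_affine(b)
    return affine_to_params(la @ lb, la @ tb + ta)


def invert_params(p: AlignmentParams) -> AlignmentParams:
    lin, t = params_to_affine(p)
    inv = lin.T  # orthogonal
    return affine_to_params(inv, -inv @ t)


def mirror_image(image: np.ndarray) -> np.ndarray:
    """Exact reflection about the vertical axis through column b/2.

    For an even box the reflection ``col -> b - col`` maps the lattice onto
    itself except for column 0, which wraps; all sampling in the package
    stays strictly inside radius b/2 - 1 so the wrapped column is never
    read.
    """
    return np.roll(image[..., ::-1], 1, axis=-1)


def apply_transform(image: np.ndarray, params: AlignmentParams) -> np.ndarray:
    """Resample ``image`` under its registration transform (bilinear).

    Out-of-frame pixels are filled with 0.  Identity parameters return the
    image unchanged (bit-exact).
    """
    if params.identity:
        return np.array(image, dtype=float, copy=True)
    img = np.asarray(image, dtype=float)
    b = img.shape[-1]
    if img.shape[-2] != b:
        raise ValueError("apply_transform expects a square image")
    c = b // 2
    lin, t = params_to_affine(params)
    inv = lin.T
    # output pixel (i, j) -> math coords v, pull back through T^{-1}.
    jj, ii = np.meshgrid(np.arange(b), np.arange(b))
    vx = jj - c
    vy = c - ii
    src = np.empty((2, b, b))
    src[0] = inv[0, 0] * (vx - t[0]) + inv[0, 1] * (vy - t[1])
    src[1] = inv[1, 0] * (vx - t[0]) + inv[1, 1] * (vy - t[1])
    rows = c - src[1]
    cols = src[0] + c
    return _bilinear(img, rows, cols)


def apply_transforms_batch(images: np.ndarray, params) -> np.ndarray:
    """Apply one registration transform per image, vectorized.

    ``params`` is a sequence of :class:`AlignmentParams` or a structured
    array with sx, sy, theta, mirror fields.  Equivalent to calling
    :func:`apply_transform` per image.
    """
    images = np.asarray(images, dtype=float)
    m, b, _ = images.shape
    c = b // 2
    if isinstance(params, np.ndarray) and params.dtype.names:
        sx = params["sx"].astype(float)
        sy = params["sy"].astype(float)
        theta = np.radians(params["theta"].astype(float))
        mir = params["mirror"].astype(int)
    else:
        sx = np.array([p.sx for p in params], dtype=float)
        sy = np.array([p.sy for p in params], dtype=float)
        theta = np.radians([p.theta for p in params])
        mir = np.array([p.mirror for p in params], dtype=int)
    ct, st = np.cos(theta), np.sin(theta)
    sign = np.where(mir == 1, -1.0, 1.0)
    # L = R M^m ; inv = L^T ; t = R s
    inv00 = ct * sign
    inv01 = st * sign
    inv10 = -st
    inv11 = ct
    tx = ct * sx - st * sy
    ty = st * sx + ct * sy
    jj, ii = np.meshgrid(np.arange(b), np.arange(b))
    vx = (jj - c)[None]
    vy = (c - ii)[None]
    dx = vx - tx[:, None, None]
    dy = vy - ty[:, None, None]
    src_x = inv00[:, None, None] * dx + inv01[:, None, None] * dy
    src_y = inv10[:, None, None] * dx + inv11[:, None, None] * dy
    rows = c - src_y
    cols = src_x + c
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr = rows - r0
    fc = cols - c0
    flat = images.reshape(m, b * b)
    base = (np.arange(m) * b * b)[:, None, None]
    out = np.zeros((m, b, b))
    for dr in (0, 1):
        for dc in (0, 1):
            rr = r0 + dr
            cc = c0 + dc
            valid = (rr >= 0) & (rr < b) & (cc >= 0) & (cc < b)
            w = (fr if dr else 1 - fr) * (fc if dc else 1 - fc) * valid
            idx = np.clip(rr, 0, b - 1) * b + np.clip(cc, 0, b - 1) + base
            out += w * flat.ravel()[idx]
    return out


def _bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    b0, b1 = img.shape[-2], img.shape[-1]
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros(rows.shape, dtype=float)
    for dr in (0, 1):
        for dc in (0, 1):
            rr = r0 + dr
            cc = c0 + dc
            w = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
            ok = (rr >= 0) & (rr < b0) & (cc >= 0) & (cc < b1)
            out[ok] += w[ok] * img[rr[ok], cc[ok]]
    return out


def pixel_error(
    a: AlignmentParams,
    b: AlignmentParams,
    radius: float,
    n_points: int = 64,
) -> float:
    """RMS displacement between two rigid transforms on a reference circle.

    The error is the root-mean-square distance, over ``n_points`` points
    placed uniformly on the circle of the given radius, between the images
    of each point under the two transforms.  A mirror mismatch is maximally
    unstable and returns ``inf``.  Closed forms: two pure translations
    differing by ``d`` give ``|d|``; two rotations differing by ``dtheta``
    give ``2 r sin(dtheta / 2)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if a.mirror != b.mirror:
        return float("inf")
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = radius * np.stack([np.cos(phi), np.sin(phi)])  # (2, n)
    la, ta = params_to_affine(a)
    lb, tb = params_to_affine(b)
    d = (la @ pts + ta[:, None]) - (lb @ pts + tb[:, None])
    return float(np.sqrt(np.mean(np.sum(d * d, axis=0))))


def replace_peak(p: AlignmentParams, peak: float) -> AlignmentParams:
    return replace(p, peak=peak)
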