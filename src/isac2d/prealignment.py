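"""One-time pre-alignment of a stack against a single global reference.

Before any clustering, every particle is iteratively aligned to one common
reference (the running global average).  Working with a single reference
keeps the cross-correlation table small, so the whole stack streams
through the aligner cheaply; by default the refinement runs a fixed 14
iterations, and the reference is re-centered after every rebuild so the
solution cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polar_align import PolarSpectra, SearchGrid, iterative_single_ref_align

DEFAULT_PREALIGN_ITERS = 14

__all__ = ["PrealignResult", "prealign", "DEFAULT_PREALIGN_ITERS"]


@dataclass
class PrealignResult:
    """Per-particle parameters and refined global average."""

    params: np.ndarray  # structured (n,) with sx, sy, theta, mirror, peak
    global_average: np.ndarray
    iterations_run: int
    mean_peak_history: list[float]
    ids: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sx": self.params["sx"],
                "sy": self.params["sy"],
                "theta": self.params["theta"],
                "mirror": self.params["mirror"],
                "peak": self.params["peak"],
            }
        )
        return df


def prealign(
    stack,
    grid: SearchGrid,
    n_iters: int = DEFAULT_PREALIGN_ITERS,
    rotation: bool = True,
    recenter: bool = True,
    spectra: PolarSpectra | None = None,
) -> PrealignResult:
    """Iteratively align all particles of a stack to one global reference.

    Each iteration aligns every particle to the current reference (a k=1
    multi-reference alignment with its reduced cross-correlation table),
    rebuilds the reference as the average of the transformed particles,
    and re-centers it on its masked center of mass.  The initial reference
    is the average of the normalized, untransformed particles.

    ``rotation=False`` restricts the search to translations only (faster;
    the full search is the default).
    """
    images = np.asarray(stack.images, dtype=float)
    if images.shape[0] < 2:
        raise ValueError("pre-alignment needs at least two particles")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    params, reference, history = iterative_single_ref_align(
        images,
        grid,
        n_iters,
        spectra=spectra,
        recenter=recenter,
        rotation=rotation,
    )
    return PrealignResult(params, reference, int(n_iters), history, np.asarray(stack.ids))
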