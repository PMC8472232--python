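"""Bead diameter characterization from confocal Z-stacks.

Bead size homogeneity is what makes the variable-height device work: a
bead population's diameter spread translates directly into the width of
its detection band.  The characterization procedure is: maximum-intensity
Z-projection of a confocal stack of mounted beads, local-mean
thresholding, connected-component particle analysis, then conversion of
particle areas to equivalent-circle diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, segmentation

__all__ = [
    "BeadPopulationStats",
    "max_projection",
    "segment_particles",
    "summarize_diameters",
]


@dataclass
class BeadPopulationStats:
    """Summary of a segmented bead population.

    Diameters are equivalent-circle diameters, d = 2 sqrt(area / pi).
    ``sd`` and ``cv`` use the sample (n-1) convention and are NaN when
    fewer than two particles were found.
    """

    areas_um2: np.ndarray
    diameters_um: np.ndarray
    n: int
    mean_um: float
    sd_um: float
    cv: float


def max_projection(zstack) -> np.ndarray:
    """Pixelwise maximum across the slices of a Z-stack."""
    stack = [np.asarray(s, dtype=float) for s in zstack]
    if not stack:
        raise ValueError("empty Z-stack")
    shapes = {s.shape for s in stack}
    if len(shapes) > 1:
        raise ValueError(f"slices have mismatched shapes: {shapes}")
    return np.max(np.stack(stack), axis=0)


def segment_particles(
    projection: np.ndarray,
    pixel_size_um: float = 1.0,
    window_radius: int = 15,
    offset: float = 0.0,
    min_area_um2: float = 0.0,
    exclude_edges: bool = True,
    connectivity: int = 2,
) -> np.ndarray:
    """Particle areas (µm²) from a maximum-intensity projection.

    Bright particles are selected by a local-mean threshold (square window
    of radius ``window_radius`` px plus ``offset``), labelled with
    8-connectivity by default, filtered by ``min_area_um2``, and — with
    ``exclude_edges`` — particles touching the image border are dropped
    (they are partially out of frame and would bias the size estimate).
    """
    proj = np.asarray(projection, dtype=float)
    if np.ptp(proj) == 0:
        return np.empty(0)
    block = 2 * window_radius + 1
    local = filters.threshold_local(proj, block_size=block, method="mean")
    # the mean filter carries O(1e-13) float error, enough to select
    # exactly-flat background under a strict ">"; compare with a
    # scale-relative tolerance
    tol = 1e-9 * float(np.ptp(proj))
    mask = proj > local + offset + tol
    if exclude_edges:
        mask = segmentation.clear_border(mask)
    labels = measure.label(mask, connectivity=connectivity)
    areas_px = np.bincount(labels.ravel())[1:]  # drop background
    areas_um2 = areas_px * pixel_size_um**2
    return areas_um2[areas_um2 >= min_area_um2]


def summarize_diameters(areas_um2) -> BeadPopulationStats:
    """Equivalent-circle diameter statistics for a set of particle areas."""
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError("no particles to summarize")
    diam = 2.0 * np.sqrt(areas / np.pi)
    mean = float(diam.mean())
    if areas.size >= 2:
        sd = float(diam.std(ddof=1))
        cv = sd / mean if mean else float("nan")
    else:
        sd = float("nan")
        cv = float("nan")
    return BeadPopulationStats(
        areas_um2=areas,
        diameters_um=diam,
        n=int(areas.size),
        mean_um=mean,
        sd_um=sd,
        cv=cv,
    )
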