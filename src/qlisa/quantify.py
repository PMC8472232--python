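"""Masked RFU/Bead-Area quantification of bead-band micrographs.

Each field of view (FOV) of a detection band is imaged twice: once with
epi-illumination (reflected light, used only to locate the beads) and once
per fluorescence detection channel.  The quantification statistic is

    RFU/Bead Area = f / b

where B' is the binary bead mask obtained by thresholding the
flat-field-corrected epi image, F' = B' ⊙ (background-corrected
fluorescence image), b = ΣB' (mask pixel count) and f = ΣF'.  Because only
pixels inside the bead mask contribute, fluorescent debris and quantum-dot
aggregates that are not tethered to a bead have exactly zero influence on
the statistic.

Per detection band, per-FOV statistics are averaged, their SEM reported as
the between-FOV variability, and — when a 0 pg/mL control run is supplied —
the control band mean is subtracted channelwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, transform

__all__ = [
    "ImagePair",
    "MaskStatistics",
    "BandMeasurement",
    "EmptyMaskError",
    "pseudo_flat_field",
    "background_correct",
    "binarize_epi",
    "rfu_per_bead_area",
    "measure_fov",
    "measure_band",
]


class EmptyMaskError(ValueError):
    """The bead mask is empty: RFU/Bead Area is undefined for this FOV."""


@dataclass
class ImagePair:
    """One field of view: an epi image plus per-channel fluorescence images.

    All images must share one shape; ``fluor`` maps detection-channel
    labels (e.g. ``"Qdot585"``) to 2-D arrays.
    """

    epi: np.ndarray
    fluor: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    band: str = ""
    fov_index: int = 0

    def __post_init__(self) -> None:
        self.epi = np.asarray(self.epi, dtype=float)
        self.fluor = {k: np.asarray(v, dtype=float) for k, v in self.fluor.items()}
        for name, img in self.fluor.items():
            if img.shape != self.epi.shape:
                raise ValueError(
                    f"channel {name!r} shape {img.shape} != epi {self.epi.shape}"
                )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted(self.fluor))


@dataclass
class MaskStatistics:
    """B', b, per-channel f, and the f/b statistic for one FOV."""

    mask: np.ndarray
    b: int
    f: dict[str, float]
    rfu_per_bead_area: dict[str, float]


@dataclass
class BandMeasurement:
    """Across-FOV summary for one detection band."""

    band: str
    channels: tuple[str, ...]
    mean: dict[str, float]
    sem: dict[str, float]
    n_fov: int
    control_subtracted: dict[str, float] | None = None
    per_fov: list[dict[str, float]] = field(default_factory=list)


# ----------------------------------------------------------------------
# corrections


def _poly2_surface(img: np.ndarray) -> np.ndarray:
    """Least-squares degree-2 polynomial illumination surface of ``img``."""
    ny, nx = img.shape
    y, x = np.mgrid[0:ny, 0:nx]
    x = (x / max(nx - 1, 1)) - 0.5
    y = (y / max(ny - 1, 1)) - 0.5
    cols = [np.ones_like(x), x, y, x * y, x**2, y**2]
    A = np.stack([c.ravel() for c in cols], axis=1)
    coeffs, *_ = np.linalg.lstsq(A, img.ravel(), rcond=None)
    return (A @ coeffs).reshape(img.shape)


def _big_gaussian(img: np.ndarray, sigma: float) -> np.ndarray:
    # direct separable convolution is slow for sigma of hundreds of px;
    # downsample, blur, and resize back (block mean keeps the DC level)
    if sigma <= 16:
        return ndimage.gaussian_filter(img, sigma, mode="reflect")
    factor = max(2, int(sigma / 8))
    factor = min(factor, min(img.shape) // 8 or 1)
    small = transform.downscale_local_mean(img, (factor, factor))
    small = ndimage.gaussian_filter(small, sigma / factor, mode="reflect")
    return transform.resize(
        small, img.shape, order=1, mode="edge", anti_aliasing=False
    )


def pseudo_flat_field(
    epi: np.ndarray,
    method: str = "polynomial",
    sigma: float | None = None,
    degree: int = 2,
) -> np.ndarray:
    """Remove slowly varying illumination from an epi image.

    The image is divided elementwise by an estimate of its own
    illumination surface, then rescaled to preserve the original global
    mean.  Two estimators are available:

    ``"polynomial"`` (default)
        Least-squares polynomial surface (degree 2).  Removes smooth
        multiplicative gradients essentially exactly, including at the
        image borders.
    ``"gaussian"``
        Large-scale Gaussian blur of the image itself (sigma defaults to a
        quarter of the smaller image dimension).  The classical
        pseudo-flat-field; accurate in the interior but biased within
        ~sigma of the borders, where any symmetric blur flattens a ramp.
    """
    epi = np.asarray(epi, dtype=float)
    if epi.size == 0:
        raise ValueError("empty image")
    if not np.any(epi):
        raise ValueError("all-zero epi image cannot be flat-field corrected")
    if method == "polynomial":
        if degree == 2:
            surface = _poly2_surface(epi)
        else:  # pragma: no cover - degree 2 is the only supported default
            raise ValueError("only degree-2 polynomial surfaces are supported")
    elif method == "gaussian":
        if sigma is None:
            sigma = min(epi.shape) / 4.0
        surface = _big_gaussian(epi, sigma)
    else:
        raise ValueError(f"unknown flat-field method {method!r}")
    surface = np.clip(surface, np.finfo(float).tiny, None)
    corrected = epi / surface
    return corrected * (epi.mean() / corrected.mean())


def background_correct(
    fluor: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Subtract the background level from a fluorescence image.

    With a bead mask supplied, the background is the median of the
    off-mask pixels; without one, the median of the lowest-decile pixels.
    Results are clamped at zero.
    """
    fluor = np.asarray(fluor, dtype=float)
    if fluor.size == 0:
        raise ValueError("empty image")
    if mask is not None:
        off = fluor[~np.asarray(mask, dtype=bool)]
        if off.size == 0:
            raise ValueError("mask covers every pixel; no background estimate")
        bg = float(np.median(off))
    else:
        cutoff = np.quantile(fluor, 0.10)
        low = fluor[fluor <= cutoff]
        bg = float(np.median(low))
    return np.clip(fluor - bg, 0.0, None)


def binarize_epi(
    epi: np.ndarray,
    method: str = "otsu",
    polarity: str = "beads_dark",
    window_radius: int = 15,
    offset: float = 0.0,
) -> np.ndarray:
    """Threshold a flat-field-corrected epi image into the bead mask B'.

    ``method="otsu"`` maximises between-class variance globally;
    ``method="local_mean"`` compares each pixel against the mean of a
    square window of radius ``window_radius`` minus ``offset``.  With
    ``polarity="beads_dark"`` (the default; beads attenuate reflected
    light) pixels *below* threshold are bead pixels.
    """
    epi = np.asarray(epi, dtype=float)
    if polarity not in ("beads_dark", "beads_bright"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if np.ptp(epi) == 0:
        warnings.warn("constant epi image: returning empty mask", stacklevel=2)
        return np.zeros(epi.shape, dtype=bool)
    if method == "otsu":
        t = filters.threshold_otsu(epi)
        return epi < t if polarity == "beads_dark" else epi > t
    if method == "local_mean":
        block = 2 * window_radius + 1
        local = filters.threshold_local(epi, block_size=block, method="mean")
        tol = 1e-9 * float(np.ptp(epi))  # mean-filter float error guard
        if polarity == "beads_dark":
            return epi < local - offset - tol
        return epi > local + offset + tol
    raise ValueError(f"unknown threshold method {method!r}")


# ----------------------------------------------------------------------
# the statistic


def rfu_per_bead_area(
    mask: np.ndarray, fluor: Mapping[str, np.ndarray]
) -> MaskStatistics:
    """The masked statistic: per channel, f = Σ(B' ⊙ F) over b = ΣB'."""
    mask = np.asarray(mask, dtype=bool)
    b = int(mask.sum())
    if b == 0:
        raise EmptyMaskError("bead mask B' is empty; f/b is undefined")
    f: dict[str, float] = {}
    ratio: dict[str, float] = {}
    for name, img in fluor.items():
        img = np.asarray(img, dtype=float)
        if img.shape != mask.shape:
            raise ValueError(f"channel {name!r} shape mismatch with mask")
        f_val = float(img[mask].sum())
        f[name] = f_val
        ratio[name] = f_val / b
    return MaskStatistics(mask=mask, b=b, f=f, rfu_per_bead_area=ratio)


def measure_fov(
    pair: ImagePair,
    flat_field_method: str = "polynomial",
    threshold_method: str = "otsu",
    polarity: str = "beads_dark",
    window_radius: int = 15,
) -> MaskStatistics:
    """Full single-FOV pipeline: flat-field -> B' -> background -> f/b."""
    corrected_epi = pseudo_flat_field(pair.epi, method=flat_field_method)
    mask = binarize_epi(
        corrected_epi,
        method=threshold_method,
        polarity=polarity,
        window_radius=window_radius,
    )
    if not mask.any():
        raise EmptyMaskError(f"no beads detected in FOV {pair.fov_index}")
    corrected = {
        name: background_correct(img, mask=mask) for name, img in pair.fluor.items()
    }
    return rfu_per_bead_area(mask, corrected)


def measure_band(
    fovs: Sequence[ImagePair],
    control_fovs: Sequence[ImagePair] | None = None,
    **fov_kwargs,
) -> BandMeasurement:
    """Aggregate per-FOV statistics for one detection band.

    The per-FOV RFU/Bead-Area values are averaged per channel; SEM is the
    between-FOV sample sd divided by sqrt(n).  When control FOVs (a
    0 pg/mL run of the same band) are supplied, the control band mean is
    subtracted channelwise; negative results are preserved as-is so that
    downstream statistics stay unbiased.
    """
    if not fovs:
        raise ValueError("need at least one FOV")
    channels = fovs[0].channels
    for p in fovs[1:]:
        if p.channels != channels:
            raise ValueError("FOVs have mismatched channel sets")

    per_fov = [measure_fov(p, **fov_kwargs).rfu_per_bead_area for p in fovs]
    mean = {c: float(np.mean([s[c] for s in per_fov])) for c in channels}
    if len(per_fov) > 1:
        sem = {
            c: float(np.std([s[c] for s in per_fov], ddof=1) / np.sqrt(len(per_fov)))
            for c in channels
        }
    else:
        sem = {c: 0.0 for c in channels}

    control_subtracted = None
    if control_fovs is not None:
        control = measure_band(list(control_fovs), None, **fov_kwargs)
        if control.channels != channels:
            raise ValueError("control FOVs have mismatched channel sets")
        control_subtracted = {c: mean[c] - control.mean[c] for c in channels}

    return BandMeasurement(
        band=fovs[0].band,
        channels=channels,
        mean=mean,
        sem=sem,
        n_fov=len(fovs),
        control_subtracted=control_subtracted,
        per_fov=per_fov,
    )
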