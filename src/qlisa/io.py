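"""Reading and writing the pipeline's on-disk formats.

Images travel as 16-bit grayscale TIFFs named ``<band>_<fov>_<channel>.tif``
(channel ``epi`` for the epi-illuminated frame); band measurements and
manifests as CSV; channel geometry as JSON (analytic) or CSV with
``position_um,height_um`` columns (profilometer trace).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .device import ChannelProfile
from .quantify import BandMeasurement, ImagePair

__all__ = [
    "save_image_pair",
    "load_image_pair",
    "list_fovs",
    "band_measurements_to_frame",
    "write_band_measurements",
    "profile_from_csv",
    "profile_to_csv",
]

_FNAME = re.compile(r"(?P<band>.+)_(?P<fov>\d+)_(?P<channel>[^_]+)\.tif$")


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def save_image_pair(pair: ImagePair, directory: str | Path) -> list[Path]:
    """Write one FOV as ``<band>_<fov>_<channel>.tif`` 16-bit files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    band = pair.band or "band"
    written = []
    for channel, img in [("epi", pair.epi), *sorted(pair.fluor.items())]:
        path = directory / f"{band}_{pair.fov_index:03d}_{channel}.tif"
        tifffile.imwrite(path, _to_uint16(img))
        written.append(path)
    return written


def list_fovs(directory: str | Path) -> pd.DataFrame:
    """Manifest of the TIFFs in a directory: band, fov, channel, path."""
    rows = []
    for path in sorted(Path(directory).glob("*.tif")):
        m = _FNAME.match(path.name)
        if m:
            rows.append(
                {
                    "band": m["band"],
                    "fov": int(m["fov"]),
                    "channel": m["channel"],
                    "path": str(path),
                }
            )
    return pd.DataFrame(rows, columns=["band", "fov", "channel", "path"])


def load_image_pair(
    directory: str | Path, band: str, fov: int, pixel_size_um: float = 1.0
) -> ImagePair:
    """Load one FOV's epi + fluorescence TIFFs back into an ImagePair."""
    directory = Path(directory)
    epi_path = directory / f"{band}_{fov:03d}_epi.tif"
    if not epi_path.exists():
        raise FileNotFoundError(epi_path)
    fluor = {}
    for path in directory.glob(f"{band}_{fov:03d}_*.tif"):
        m = _FNAME.match(path.name)
        if m and m["channel"] != "epi":
            fluor[m["channel"]] = tifffile.imread(path).astype(float)
    return ImagePair(
        epi=tifffile.imread(epi_path).astype(float),
        fluor=fluor,
        pixel_size_um=pixel_size_um,
        band=band,
        fov_index=fov,
    )


def band_measurements_to_frame(
    measurements: Sequence[BandMeasurement],
) -> pd.DataFrame:
    """Long-format table: one row per band x channel."""
    rows = []
    for m in measurements:
        for ch in m.channels:
            rows.append(
                {
                    "band": m.band,
                    "channel": ch,
                    "rfu_per_bead_area": m.mean[ch],
                    "sem": m.sem[ch],
                    "n_fov": m.n_fov,
                    "control_subtracted": (
                        m.control_subtracted[ch]
                        if m.control_subtracted is not None
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def write_band_measurements(
    measurements: Sequence[BandMeasurement], path: str | Path
) -> None:
    band_measurements_to_frame(measurements).to_csv(path, index=False)


def profile_from_csv(path: str | Path, width_um: float = 3000.0) -> ChannelProfile:
    """Measured channel profile from ``position_um,height_um`` CSV."""
    df = pd.read_csv(path)
    samples = tuple(zip(df["position_um"].astype(float), df["height_um"].astype(float)))
    return ChannelProfile(
        length_um=float(df["position_um"].iloc[-1]),
        width_um=width_um,
        inlet_um=float(df["height_um"].iloc[0]),
        outlet_um=float(df["height_um"].iloc[-1]),
        kind="measured",
        samples=samples,
    )


def profile_to_csv(profile: ChannelProfile, path: str | Path, n: int = 101) -> None:
    xs = np.linspace(0, profile.length_um, n)
    from .device import height_at

    pd.DataFrame(
        {"position_um": xs, "height_um": [height_at(profile, x) for x in xs]}
    ).to_csv(path, index=False)
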