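"""Synthetic bead-band micrograph generator with known ground truth.

No raw micrographs are publicly available for the variable-height bead
immunoassay, so every downstream stage (masking, the RFU/Bead-Area
statistic, standard curves, LOD/CV estimation, crossover analysis) is
exercised against this generative model instead.  A rendered field of view
emulates the real instrument's data:

* a population of beads of the band's nominal diameter (truncated-normal
  size distribution), placed without overlap;
* an epi-illumination image in which beads attenuate a bright background,
  under a smooth multiplicative illumination gradient and camera noise;
* one fluorescence image per detection channel, where each bead carries a
  concentration-dependent quantum-dot signal (Hill-type saturating binding
  response), spread across channels by a spectral crossover matrix, plus
  bead-type-specific autofluorescence;
* untethered debris: small bright fluorescent spots absent from the epi
  image (so a correct masked statistic must ignore them);
* physical carryover: smaller bead types occasionally lodging in an
  upstream band.

Every random quantity is drawn from a seeded generator and recorded in a
:class:`GroundTruth` object, so recovery can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np

from .device import BeadSpec
from .quantify import ImagePair

__all__ = [
    "BindingModel",
    "SimConfig",
    "GroundTruth",
    "default_two_plex_config",
    "default_three_plex_config",
    "default_single_plex_config",
    "sample_bead_diameters",
    "mean_response",
    "render_fov",
    "simulate_standard_curve_run",
    "simulate_multiplex_run",
]


@dataclass(frozen=True)
class BindingModel:
    """Monotone saturating concentration -> signal response (Hill form).

    response(c) = baseline + response_max * c^hill / (k_half^hill + c^hill)

    ``baseline`` is the per-bead signal at 0 pg/mL (non-specific binding),
    ``response_max`` the saturating specific signal, ``k_half`` the
    half-saturation concentration in pg/mL and ``hill`` the cooperativity.
    """

    response_max: float = 2000.0
    k_half: float = 2000.0
    baseline: float = 50.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if min(self.response_max, self.k_half, self.hill) <= 0 or self.baseline < 0:
            raise ValueError("binding model parameters must be positive")


def mean_response(concentration: float, model: BindingModel) -> float:
    """Expected per-bead fluorescence (RFU per bead-area unit)."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    c = float(concentration)
    if c == 0.0:
        return model.baseline
    num = c**model.hill
    return model.baseline + model.response_max * num / (
        model.k_half**model.hill + num
    )


# default three-analyte traumatic-brain-injury biomarker panel:
# ~4.5 µm beads (IL-6, Qdot525), ~2.8 µm (GFAP, Qdot585), ~1 µm (IL-8,
# Qdot655).  The 2.8 µm beads autofluoresce strongly in the 525 channel.
_DEFAULT_SPECS = (
    BeadSpec("IL-6", 4.5, 0.03, "Qdot525"),
    BeadSpec("GFAP", 2.8, 0.03, "Qdot585"),
    BeadSpec("IL-8", 1.0, 0.05, "Qdot655"),
)
_DEFAULT_CHANNELS = ("Qdot525", "Qdot585", "Qdot655")


def _default_crossover(channels: Sequence[str], bleed: float = 0.02):
    return {
        f: {c: (1.0 if c == f else bleed) for c in channels} for f in channels
    }


@dataclass
class SimConfig:
    """Full generative description of a simulated assay run.

    The defaults describe the study conditions this generator emulates:
    1344 x 1100 px 16-bit-range camera frames, three bead populations of
    nominal diameter 4.5 / 2.8 / 1 µm read out on Qdot 525 / 585 / 655
    channels, ~2% spectral bleed between channels, strong 525 nm
    autofluorescence of the 2.8 µm beads, a mild (~±10–17%) illumination
    tilt on the epi path, Gaussian camera noise, a handful of untethered
    debris spots per FOV, and 5% physical bead carryover into upstream
    bands.
    """

    seed: int = 0
    image_shape: tuple[int, int] = (1100, 1344)  # rows, cols
    pixel_size_um: float = 0.454
    bead_specs: tuple[BeadSpec, ...] = _DEFAULT_SPECS
    beads_per_fov: int = 200
    binding_model: BindingModel = field(default_factory=BindingModel)
    channels: tuple[str, ...] = _DEFAULT_CHANNELS
    crossover: dict = field(default_factory=lambda: _default_crossover(_DEFAULT_CHANNELS))
    autofluorescence: dict = field(
        default_factory=lambda: {"GFAP": {"Qdot525": 80.0}}
    )
    illumination: dict = field(default_factory=lambda: {"x": 0.20, "y": -0.15})
    epi_background: float = 1000.0
    epi_attenuation: float = 400.0
    epi_noise_sd: float = 10.0
    fluor_background: float = 20.0
    fluor_noise_sd: float = 5.0
    poisson_gain: float = 0.0  # >0 adds shot noise: gain * Poisson(img/gain)
    bead_brightness_cv: float = 0.10
    fov_effect_cv: float = 0.05  # per-FOV multiplicative response jitter
    replicate_effect_cv: float = 0.05  # per-replicate (run-level) jitter
    edge_width_px: float = 0.25  # rim softness of rendered disks
    debris_per_fov: float = 30.0
    debris_intensity: tuple[float, float] = (200.0, 2000.0)
    debris_radius_px: tuple[float, float] = (1.0, 3.0)
    carryover_fraction: float = 0.05
    n_fov: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.carryover_fraction < 1):
            raise ValueError("carryover_fraction must lie in [0, 1)")
        for name in (
            "epi_background",
            "epi_attenuation",
            "epi_noise_sd",
            "fluor_background",
            "fluor_noise_sd",
            "poisson_gain",
            "bead_brightness_cv",
            "fov_effect_cv",
            "replicate_effect_cv",
            "debris_per_fov",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        labels = [b.label for b in self.bead_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("bead spec labels must be unique")

    def spec_for(self, label: str) -> BeadSpec:
        for b in self.bead_specs:
            if b.label == label:
                return b
        raise KeyError(f"no bead spec labelled {label!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bead_specs"] = [asdict(b) for b in self.bead_specs]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "bead_specs" in d:
            d["bead_specs"] = tuple(BeadSpec(**b) for b in d["bead_specs"])
        if "binding_model" in d and isinstance(d["binding_model"], Mapping):
            d["binding_model"] = BindingModel(**d["binding_model"])
        for key in ("image_shape", "channels", "debris_intensity", "debris_radius_px"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def default_single_plex_config(**overrides) -> SimConfig:
    """A GFAP-style single-analyte configuration (2.8 µm beads, Qdot585)."""
    cfg = SimConfig(
        bead_specs=(BeadSpec("GFAP", 2.8, 0.03, "Qdot585"),),
        channels=("Qdot585",),
        crossover=_default_crossover(("Qdot585",)),
        autofluorescence={},
        **overrides,
    )
    return cfg


def default_two_plex_config(**overrides) -> SimConfig:
    """IL-6 (4.5 µm, Qdot525) + GFAP (2.8 µm, Qdot585) two-colour panel."""
    channels = ("Qdot525", "Qdot585")
    return SimConfig(
        bead_specs=(
            BeadSpec("IL-6", 4.5, 0.03, "Qdot525"),
            BeadSpec("GFAP", 2.8, 0.03, "Qdot585"),
        ),
        channels=channels,
        crossover=_default_crossover(channels),
        autofluorescence={"GFAP": {"Qdot525": 80.0}},
        **overrides,
    )


def default_three_plex_config(**overrides) -> SimConfig:
    """IL-6 + GFAP + IL-8 three-colour panel (4.5 / 2.8 / 1 µm beads)."""
    return SimConfig(**overrides)


@dataclass
class GroundTruth:
    """Everything the renderer drew, for exact downstream checking."""

    band: str
    concentrations: dict[str, float]
    centers_px: np.ndarray  # (n, 2) row, col
    radii_px: np.ndarray
    bead_labels: list[str]
    channel_signals: np.ndarray  # (n_beads, n_channels) noiseless per-bead RFU
    channels: tuple[str, ...]
    mask: np.ndarray
    true_rfu_per_bead_area: dict[str, float]
    fov_factor: float
    replicate_factor: float


# ----------------------------------------------------------------------
# sampling


def sample_bead_diameters(
    spec: BeadSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` bead diameters (µm): normal(mean, cv*mean), truncated ±3 sd."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mean = spec.diameter_mean
    sd = spec.diameter_cv * mean
    if sd == 0 or n == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[np.abs(draw - mean) <= 3 * sd][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _sub_seed(master: int, *counters: int) -> np.random.Generator:
    """Deterministic sub-stream: SeedSequence keyed by (master, counters)."""
    return np.random.default_rng(np.random.SeedSequence([int(master), *map(int, counters)]))


def _illumination_field(shape: tuple[int, int], coeffs: Mapping[str, float]) -> np.ndarray:
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    xn = x / max(nx - 1, 1) - 0.5
    yn = y / max(ny - 1, 1) - 0.5
    f = (
        1.0
        + coeffs.get("x", 0.0) * xn
        + coeffs.get("y", 0.0) * yn
        + coeffs.get("xx", 0.0) * xn**2
        + coeffs.get("yy", 0.0) * yn**2
    )
    return np.clip(f, 0.05, None)


def _place_beads(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: np.ndarray,
    max_tries: int = 200,
) -> np.ndarray:
    """Random non-overlapping centres for disks of the given radii (px)."""
    ny, nx = shape
    centers = np.empty((len(radii), 2))
    placed_r: list[float] = []
    for i, r in enumerate(radii):
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r + 1, ny - r - 1)
            cx = rng.uniform(r + 1, nx - r - 1)
            if i:
                d2 = ((centers[:i, 0] - cy) ** 2 + (centers[:i, 1] - cx) ** 2)
                min_d = (np.asarray(placed_r) + r + 1.0) ** 2
                if np.any(d2 < min_d):
                    continue
            centers[i] = (cy, cx)
            placed_r.append(float(r))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place bead {i} of {len(radii)} without overlap; "
                "reduce beads_per_fov or enlarge the image"
            )
    return centers


def _add_disk(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    r: float,
    value: float,
    edge_width: float = 1.0,
) -> None:
    """Accumulate an antialiased disk onto canvas.

    ``edge_width`` is the width (px) of the linear intensity ramp at the
    disk rim; the ramp is centred on the geometric radius so the rendered
    area matches pi r^2 regardless of the softness.
    """
    ny, nx = canvas.shape
    pad = edge_width / 2 + 2
    y0, y1 = max(0, int(cy - r - pad)), min(ny, int(cy + r + pad + 1))
    x0, x1 = max(0, int(cx - r - pad)), min(nx, int(cx + r + pad + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    coverage = np.clip((r - dist) / edge_width + 0.5, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += value * coverage


# ----------------------------------------------------------------------
# rendering


def render_fov(
    config: SimConfig,
    band: str,
    concentrations: Mapping[str, float],
    seed: int,
    fov_index: int = 0,
    replicate_factor: float | None = None,
) -> tuple[ImagePair, GroundTruth]:
    """Render one field of view of the detection band for bead type ``band``.

    ``concentrations`` maps analyte labels to pg/mL.  Beads of the band's
    own type dominate; smaller bead types from the same panel appear with
    expectation ``carryover_fraction * beads_per_fov`` each (physical
    carryover).  ``replicate_factor`` carries the run-level response
    jitter shared by all FOVs of one replicate (drawn here if omitted).
    """
    band_spec = config.spec_for(band)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    shape = tuple(config.image_shape)

    if replicate_factor is None:
        replicate_factor = float(
            rng.lognormal(0.0, config.replicate_effect_cv)
            if config.replicate_effect_cv
            else 1.0
        )
    fov_factor = float(
        rng.lognormal(0.0, config.fov_effect_cv) if config.fov_effect_cv else 1.0
    )

    # bead roster: band's own beads + carryover of strictly smaller types
    labels: list[str] = [band] * config.beads_per_fov
    for other in config.bead_specs:
        if other.label == band:
            continue
        if other.diameter_mean < band_spec.diameter_mean and config.carryover_fraction:
            n_carry = rng.poisson(config.carryover_fraction * config.beads_per_fov)
            labels.extend([other.label] * n_carry)

    diameters = np.concatenate(
        [
            sample_bead_diameters(config.spec_for(lbl), 1, rng)
            for lbl in labels
        ]
    ) if labels else np.empty(0)
    radii_px = diameters / 2.0 / config.pixel_size_um
    centers = _place_beads(rng, shape, radii_px)

    # per-bead, per-channel noiseless signal (RFU per unit bead area)
    n_beads = len(labels)
    signals = np.zeros((n_beads, len(config.channels)))
    for i, lbl in enumerate(labels):
        spec = config.spec_for(lbl)
        conc = float(concentrations.get(lbl, 0.0))
        qdot = mean_response(conc, config.binding_model)
        qdot *= replicate_factor * fov_factor
        if config.bead_brightness_cv:
            qdot *= rng.lognormal(0.0, config.bead_brightness_cv)
        row = config.crossover.get(spec.fluor_channel, {})
        auto = config.autofluorescence.get(lbl, {})
        for j, ch in enumerate(config.channels):
            signals[i, j] = qdot * row.get(ch, 0.0) + auto.get(ch, 0.0)

    # --- epi image ---------------------------------------------------
    ew = config.edge_width_px
    attenuation = np.zeros(shape)
    for (cy, cx), r in zip(centers, radii_px):
        _add_disk(attenuation, cy, cx, r, 1.0, ew)
    illum = _illumination_field(shape, config.illumination)
    epi = illum * (
        config.epi_background
        - config.epi_attenuation * np.clip(attenuation, 0.0, 1.0)
    )
    if config.epi_noise_sd:
        epi = epi + rng.normal(0.0, config.epi_noise_sd, shape)
    epi = np.clip(epi, 0.0, None)

    # --- fluorescence channels ---------------------------------------
    fluor: dict[str, np.ndarray] = {}
    coverage_total = attenuation  # reuse: sum of per-bead coverages
    for j, ch in enumerate(config.channels):
        img = np.zeros(shape)
        for i, ((cy, cx), r) in enumerate(zip(centers, radii_px)):
            if signals[i, j]:
                _add_disk(img, cy, cx, r, signals[i, j], ew)
        fluor[ch] = img

    # debris: bright fluorescent specks not present in the epi image
    n_debris = int(rng.poisson(config.debris_per_fov)) if config.debris_per_fov else 0
    for _ in range(n_debris):
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        r = rng.uniform(*config.debris_radius_px)
        inten = rng.uniform(*config.debris_intensity)
        f_ch = config.channels[rng.integers(len(config.channels))]
        row = config.crossover.get(f_ch, {f_ch: 1.0})
        for ch in config.channels:
            gain = row.get(ch, 0.0)
            if gain:
                _add_disk(fluor[ch], cy, cx, r, inten * gain, ew)

    for ch in config.channels:
        img = fluor[ch] + config.fluor_background
        if config.poisson_gain > 0:
            img = config.poisson_gain * rng.poisson(
                np.clip(img, 0.0, None) / config.poisson_gain
            ).astype(float)
        if config.fluor_noise_sd:
            img = img + rng.normal(0.0, config.fluor_noise_sd, shape)
        fluor[ch] = np.clip(img, 0.0, None)

    mask = coverage_total >= 0.5
    areas = np.pi * radii_px**2
    total_area = areas.sum() if n_beads else 1.0
    true_rfu = {
        ch: float((signals[:, j] * areas).sum() / total_area)
        for j, ch in enumerate(config.channels)
    }

    pair = ImagePair(
        epi=epi,
        fluor=fluor,
        pixel_size_um=config.pixel_size_um,
        band=band,
        fov_index=fov_index,
    )
    truth = GroundTruth(
        band=band,
        concentrations=dict(concentrations),
        centers_px=centers,
        radii_px=radii_px,
        bead_labels=labels,
        channel_signals=signals,
        channels=tuple(config.channels),
        mask=mask,
        true_rfu_per_bead_area=true_rfu,
        fov_factor=fov_factor,
        replicate_factor=replicate_factor,
    )
    return pair, truth


def render_sizing_projection(
    spec: BeadSpec,
    n: int,
    seed: int,
    pixel_size_um: float = 0.1,
    shape: tuple[int, int] | None = None,
    intensity: float = 1000.0,
    noise_sd: float = 0.0,
    min_gap_px: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic maximum-intensity projection of mounted beads.

    Emulates the confocal bead-characterization input: bright antialiased
    disks of truncated-normal diameters on a dark background, placed with
    ``min_gap_px`` clearance so particles never touch.  Returns
    ``(projection, true_diameters_um)``.  Confocal sampling is finer than
    the assay camera, hence the 0.1 µm/px default.
    """
    rng = np.random.default_rng(seed)
    diameters = sample_bead_diameters(spec, n, rng)
    radii_px = diameters / 2.0 / pixel_size_um
    if shape is None:
        # size the field so ~15% is covered by beads
        area = np.pi * (radii_px**2).sum() / 0.15
        side = int(np.sqrt(area)) + int(4 * radii_px.max())
        shape = (side, side)
    # reuse the non-overlap placement with a widened exclusion radius
    centers = _place_beads(rng, shape, radii_px + min_gap_px / 2.0)
    img = np.zeros(shape)
    for (cy, cx), r in zip(centers, radii_px):
        _add_disk(img, cy, cx, r, intensity, edge_width=1.0)
    if noise_sd:
        img = np.clip(img + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return img, diameters


# ----------------------------------------------------------------------
# experiment-level generators


@dataclass
class Measurement:
    """One concentration x replicate image set (n_fov FOVs of one band)."""

    band: str
    concentration: float
    replicate: int
    is_blank: bool
    fovs: list[ImagePair]
    truths: list[GroundTruth]


#: Standard calibrator series used for the single-analyte runs (pg/mL).
DEFAULT_CALIBRATORS = (10000.0, 5000.0, 1000.0, 500.0, 100.0, 0.0)
#: Blank replicate count used for limit-of-detection estimation.
DEFAULT_N_BLANKS = 10


def simulate_standard_curve_run(
    concentrations: Sequence[float] = DEFAULT_CALIBRATORS,
    replicates: int = 3,
    config: SimConfig | None = None,
    analyte: str | None = None,
    n_blanks: int = DEFAULT_N_BLANKS,
) -> Iterator[Measurement]:
    """Yield the image sets of a calibration run, one measurement at a time.

    One image set (``config.n_fov`` FOVs) per concentration x replicate,
    plus ``n_blanks`` independent blank (0 pg/mL) replicates for LOD
    estimation.  Sub-seeds derive deterministically from ``config.seed``
    and a (kind, concentration-index, replicate) counter, so any subset is
    independently reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if config is None:
        config = default_single_plex_config()
    if analyte is None:
        analyte = config.bead_specs[0].label

    for ci, conc in enumerate(concentrations):
        for rep in range(replicates):
            rng = _sub_seed(config.seed, 1, ci, rep)
            rep_factor = float(
                rng.lognormal(0.0, config.replicate_effect_cv)
                if config.replicate_effect_cv
                else 1.0
            )
            fovs, truths = [], []
            for k in range(config.n_fov):
                pair, truth = render_fov(
                    config,
                    analyte,
                    {analyte: conc},
                    seed=rng,
                    fov_index=k,
                    replicate_factor=rep_factor,
                )
                fovs.append(pair)
                truths.append(truth)
            yield Measurement(analyte, float(conc), rep, False, fovs, truths)

    for bi in range(n_blanks):
        rng = _sub_seed(config.seed, 2, bi, 0)
        rep_factor = float(
            rng.lognormal(0.0, config.replicate_effect_cv)
            if config.replicate_effect_cv
            else 1.0
        )
        fovs, truths = [], []
        for k in range(config.n_fov):
            pair, truth = render_fov(
                config,
                analyte,
                {analyte: 0.0},
                seed=rng,
                fov_index=k,
                replicate_factor=rep_factor,
            )
            fovs.append(pair)
            truths.append(truth)
        yield Measurement(analyte, 0.0, bi, True, fovs, truths)


def simulate_multiplex_run(
    sample: Mapping[str, float],
    config: SimConfig | None = None,
    with_controls: bool = True,
    n_fov: int | None = None,
) -> Iterator[tuple[str, Measurement, Measurement | None]]:
    """Yield per-band image sets for a multiplex sample.

    ``sample`` maps analyte labels to concentrations (every panel analyte
    must appear).  Bands are emitted in order of decreasing bead diameter
    — the order they appear along the channel.  With ``with_controls``
    each band also gets an all-blank control run for control subtraction.
    """
    if config is None:
        config = default_two_plex_config()
    missing = {b.label for b in config.bead_specs} - set(sample)
    if missing:
        raise ValueError(f"sample missing analytes: {sorted(missing)}")
    n = n_fov if n_fov is not None else config.n_fov
    blank = {b.label: 0.0 for b in config.bead_specs}

    ordered = sorted(config.bead_specs, key=lambda b: -b.diameter_mean)
    for bi, spec in enumerate(ordered):
        rng = _sub_seed(config.seed, 3, bi, 0)
        fovs, truths = [], []
        for k in range(n):
            pair, truth = render_fov(
                config, spec.label, dict(sample), seed=rng, fov_index=k
            )
            fovs.append(pair)
            truths.append(truth)
        meas = Measurement(spec.label, sample[spec.label], 0, False, fovs, truths)
        control = None
        if with_controls:
            crng = _sub_seed(config.seed, 4, bi, 0)
            cfovs, ctruths = [], []
            for k in range(n):
                pair, truth = render_fov(
                    config, spec.label, blank, seed=crng, fov_index=k
                )
                cfovs.append(pair)
                ctruths.append(truth)
            control = Measurement(spec.label, 0.0, 0, True, cfovs, ctruths)
        yield spec.label, meas, control
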