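"""Variable-height channel geometry and flow physics.

A variable-height channel is a single wide, shallow microchannel whose
ceiling height decreases monotonically from inlet to outlet.  A suspension
of antibody-coated beads flowing through it passively sorts by size: each
bead travels until the local channel height matches its diameter and is
trapped there, so every bead population forms a distinct detection band at
a predictable position.  This module answers the design questions for such
a device:

* where does a bead of a given diameter trap (``band_position``),
* is a multiplex panel of bead sizes geometrically feasible
  (``plan_layout``, ``capacity``),
* how fast does sample flow through a given height profile
  (``flow_rate``, lubrication / wide-slit approximation), and
* does the geometry respect the empirical design rule that the outlet
  must be at least 1.5 µm high (``design_check``).

Lengths are micrometres throughout; pressures Pa; viscosities Pa·s;
volumetric flow is reported in µL/min.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "ChannelProfile",
    "BeadSpec",
    "TrapStatus",
    "BandPlacement",
    "BandLayout",
    "LayoutError",
    "MIN_OUTLET_HEIGHT_UM",
    "height_at",
    "band_position",
    "plan_layout",
    "capacity",
    "flow_rate",
    "hydraulic_resistance",
    "design_check",
]

#: Minimum recommended outlet height (µm).  Below this the flow rate drops to
#: the point where detection bands take tens of minutes to form and beads
#: begin to aggregate and adsorb onto the channel walls.
MIN_OUTLET_HEIGHT_UM = 1.5

# Beads whose diameters differ by less than this are considered
# indistinguishable by the device (they would trap in overlapping bands).
_DIAMETER_RESOLUTION_UM = 0.01


class TrapStatus(str, enum.Enum):
    """Fate of a bead population introduced at the channel inlet."""

    TRAPPED = "trapped"
    EXCLUDED_AT_INLET = "excluded_at_inlet"
    PASSES_THROUGH = "passes_through"


class LayoutError(ValueError):
    """A multiplex band layout is infeasible (e.g. duplicate bead sizes)."""


@dataclass(frozen=True)
class ChannelProfile:
    """Geometry of one variable-height channel.

    Parameters
    ----------
    length_um, width_um
        In-plane channel dimensions.  The devices modelled here are
        3 mm wide and 2 cm long.
    inlet_um, outlet_um
        Channel heights at x=0 and x=length.  Must satisfy
        ``inlet_um > outlet_um > 0``.
    kind
        ``"linear"`` (default) interpolates linearly between inlet and
        outlet; ``"measured"`` uses a profilometer trace supplied in
        ``samples``.
    samples
        For measured profiles: ordered ``(position_um, height_um)`` pairs.
        Heights must be monotone non-increasing and bracket the stated
        inlet/outlet heights within ``tolerance_um``.
    """

    length_um: float
    width_um: float
    inlet_um: float
    outlet_um: float
    kind: str = "linear"
    samples: tuple[tuple[float, float], ...] = ()
    tolerance_um: float = 0.05

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("channel length and width must be positive")
        # equality permitted: a uniform slit is a valid (degenerate)
        # profile for flow calculations, though nothing traps in it
        if not (self.inlet_um >= self.outlet_um > 0):
            raise ValueError(
                "heights must satisfy inlet >= outlet > 0; got "
                f"inlet={self.inlet_um}, outlet={self.outlet_um}"
            )
        if self.kind not in ("linear", "measured"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "measured":
            if len(self.samples) < 2:
                raise ValueError("measured profile needs >= 2 samples")
            pos = np.asarray([p for p, _ in self.samples], dtype=float)
            hts = np.asarray([h for _, h in self.samples], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError("sample positions must strictly increase")
            if np.any(np.diff(hts) > 0):
                raise ValueError("measured heights must be non-increasing")
            if pos[0] != 0 or pos[-1] != self.length_um:
                raise ValueError("samples must span [0, length_um]")
            if abs(hts[0] - self.inlet_um) > self.tolerance_um:
                raise ValueError("first sample height disagrees with inlet_um")
            if abs(hts[-1] - self.outlet_um) > self.tolerance_um:
                raise ValueError("last sample height disagrees with outlet_um")

    # -- convenience ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "length_um": self.length_um,
            "width_um": self.width_um,
            "inlet_um": self.inlet_um,
            "outlet_um": self.outlet_um,
            "kind": self.kind,
        }
        if self.samples:
            payload["samples"] = [list(s) for s in self.samples]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChannelProfile":
        d = json.loads(text)
        samples = tuple(tuple(s) for s in d.get("samples", ()))
        return cls(
            length_um=d["length_um"],
            width_um=d["width_um"],
            inlet_um=d["inlet_um"],
            outlet_um=d["outlet_um"],
            kind=d.get("kind", "linear"),
            samples=samples,
        )


@dataclass(frozen=True)
class BeadSpec:
    """One bead population / analyte in the multiplex panel.

    ``diameter_mean`` is the nominal bead diameter in µm, ``diameter_cv``
    the coefficient of variation of the bead-to-bead diameter
    distribution, and ``fluor_channel`` the name of the detection
    fluorophore conjugated to this assay (e.g. ``"Qdot585"``).
    """

    label: str
    diameter_mean: float
    diameter_cv: float = 0.0
    fluor_channel: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if not (0 <= self.diameter_cv < 0.5):
            raise ValueError("diameter_cv must lie in [0, 0.5)")


@dataclass(frozen=True)
class BandPlacement:
    bead: BeadSpec
    status: TrapStatus
    position_um: float | None  # None unless trapped (0.0 for inlet exclusion)


@dataclass
class BandLayout:
    """Result of planning a multiplex panel on one channel."""

    profile: ChannelProfile
    placements: list[BandPlacement]
    band_width_um: float
    min_separation_um: float
    separations_um: list[tuple[str, str, float]] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return not self.violations and all(
            p.status is TrapStatus.TRAPPED for p in self.placements
        )


# ----------------------------------------------------------------------
# geometry


def height_at(profile: ChannelProfile, x_um: float) -> float:
    """Channel height (µm) at distance ``x_um`` from the inlet."""
    if not (0 <= x_um <= profile.length_um):
        raise ValueError(
            f"x={x_um} µm outside channel [0, {profile.length_um}] µm"
        )
    if profile.kind == "linear":
        frac = x_um / profile.length_um
        return profile.inlet_um + (profile.outlet_um - profile.inlet_um) * frac
    pos = np.asarray([p for p, _ in profile.samples], dtype=float)
    hts = np.asarray([h for _, h in profile.samples], dtype=float)
    return float(np.interp(x_um, pos, hts))


def band_position(
    profile: ChannelProfile, diameter_um: float
) -> tuple[float | None, TrapStatus]:
    """Where a bead of ``diameter_um`` ends up in the channel.

    Returns ``(position, status)``.  Beads at least as large as the inlet
    height never enter (position 0.0, ``EXCLUDED_AT_INLET``); beads no
    larger than the outlet height flow straight through (position ``None``,
    ``PASSES_THROUGH``); otherwise the bead traps at the unique x where the
    local height equals its diameter.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    if diameter_um >= profile.inlet_um:
        return 0.0, TrapStatus.EXCLUDED_AT_INLET
    if diameter_um <= profile.outlet_um:
        return None, TrapStatus.PASSES_THROUGH
    if profile.kind == "linear":
        x = (
            (profile.inlet_um - diameter_um)
            / (profile.inlet_um - profile.outlet_um)
            * profile.length_um
        )
        return float(x), TrapStatus.TRAPPED
    # measured profile: invert the monotone piecewise-linear height trace
    pos = np.asarray([p for p, _ in profile.samples], dtype=float)
    hts = np.asarray([h for _, h in profile.samples], dtype=float)
    # np.interp needs increasing x-coordinates; heights decrease with
    # position, so interpolate position against reversed heights.  Flat
    # segments (equal heights) resolve to the most-upstream matching point.
    x = float(np.interp(diameter_um, hts[::-1], pos[::-1]))
    return x, TrapStatus.TRAPPED


def plan_layout(
    profile: ChannelProfile,
    beads: Sequence[BeadSpec],
    band_width_um: float = 500.0,
    min_separation_um: float = 500.0,
) -> BandLayout:
    """Plan detection-band positions for a multiplex bead panel.

    Beads are placed by :func:`band_position`; a violation is recorded for
    every pair of trapped bands whose centre-to-centre distance is below
    ``band_width_um + min_separation_um``, for any bead that fails to trap,
    and for an outlet below the 1.5 µm design rule.
    """
    if not beads:
        raise LayoutError("bead panel is empty")
    for i, a in enumerate(beads):
        for b in list(beads)[i + 1 :]:
            if abs(a.diameter_mean - b.diameter_mean) < _DIAMETER_RESOLUTION_UM:
                raise LayoutError(
                    f"duplicate bead diameter: {a.label!r} and {b.label!r} "
                    f"both ~{a.diameter_mean} µm cannot form distinct bands"
                )

    ordered = sorted(beads, key=lambda b: -b.diameter_mean)
    placements: list[BandPlacement] = []
    for bead in ordered:
        x, status = band_position(profile, bead.diameter_mean)
        placements.append(BandPlacement(bead=bead, status=status, position_um=x))

    layout = BandLayout(
        profile=profile,
        placements=placements,
        band_width_um=band_width_um,
        min_separation_um=min_separation_um,
    )
    trapped = [p for p in placements if p.status is TrapStatus.TRAPPED]
    for p in placements:
        if p.status is TrapStatus.EXCLUDED_AT_INLET:
            layout.violations.append(
                f"{p.bead.label}: diameter {p.bead.diameter_mean} µm >= inlet "
                f"height {profile.inlet_um} µm (excluded at inlet)"
            )
        elif p.status is TrapStatus.PASSES_THROUGH:
            layout.violations.append(
                f"{p.bead.label}: diameter {p.bead.diameter_mean} µm <= outlet "
                f"height {profile.outlet_um} µm (passes through)"
            )
    for a, b in zip(trapped, trapped[1:]):
        sep = abs(b.position_um - a.position_um)
        layout.separations_um.append((a.bead.label, b.bead.label, sep))
        if sep < band_width_um + min_separation_um:
            layout.violations.append(
                f"bands {a.bead.label}/{b.bead.label} only {sep:.0f} µm apart "
                f"(< {band_width_um + min_separation_um:.0f} µm required)"
            )
    layout.violations.extend(design_check(profile))
    return layout


def capacity(
    length_um: float, band_width_um: float = 500.0, min_separation_um: float = 500.0
) -> int:
    """Maximum number of detection bands a channel of given length holds.

    Each band occupies ``band_width_um`` and must be followed by
    ``min_separation_um`` of clear channel, so the count is
    ``floor(length / (band_width + min_separation))``.  A 20 mm channel with
    500 µm bands and 500 µm separations accommodates 20 bands.
    """
    if length_um <= 0 or band_width_um <= 0 or min_separation_um <= 0:
        raise ValueError("capacity arguments must be positive")
    return int(math.floor(length_um / (band_width_um + min_separation_um)))


# ----------------------------------------------------------------------
# flow


def _resistance_si(profile: ChannelProfile, viscosity_pa_s: float) -> float:
    """Hydraulic resistance (Pa·s/m³) in the lubrication limit.

    R = 12 µ ∫0^L dx / (w h(x)^3), valid when width >> height (the devices
    here are ~3 mm wide and a few µm high).  Linear profiles use the closed
    form; measured profiles integrate the piecewise-linear trace segment by
    segment with the same closed form per segment.
    """
    w = profile.width_um * 1e-6
    L = profile.length_um * 1e-6

    def segment_integral(dx: float, h0: float, h1: float) -> float:
        # ∫ dx/h³ over a segment where h varies linearly h0 -> h1 (metres)
        if abs(h1 - h0) < 1e-15:
            return dx / h0**3
        return dx * (1.0 / h1**2 - 1.0 / h0**2) / (2.0 * (h0 - h1))

    if profile.kind == "linear":
        integral = segment_integral(
            L, profile.inlet_um * 1e-6, profile.outlet_um * 1e-6
        )
    else:
        integral = 0.0
        pts = [(p * 1e-6, h * 1e-6) for p, h in profile.samples]
        for (x0, h0), (x1, h1) in zip(pts, pts[1:]):
            integral += segment_integral(x1 - x0, h0, h1)
    return 12.0 * viscosity_pa_s * integral / w


def hydraulic_resistance(profile: ChannelProfile, viscosity_pa_s: float) -> float:
    """Lubrication-limit hydraulic resistance in Pa·s/m³."""
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be positive")
    return _resistance_si(profile, viscosity_pa_s)


def flow_rate(
    profile: ChannelProfile, pressure_drop_pa: float, viscosity_pa_s: float
) -> float:
    """Volumetric flow rate (µL/min) driven by ``pressure_drop_pa``.

    Q = ΔP / R with R the lubrication resistance.  In the uniform-height
    limit this reduces to the plane-Poiseuille slit formula
    Q = w h³ ΔP / (12 µ L).
    """
    if pressure_drop_pa <= 0:
        raise ValueError("pressure drop must be positive")
    q_si = pressure_drop_pa / hydraulic_resistance(profile, viscosity_pa_s)
    return q_si * 1e9 * 60.0  # m³/s -> µL/min


def resistance_quadrature_oracle(
    profile: ChannelProfile, viscosity_pa_s: float
) -> float:
    """Adaptive-quadrature evaluation of the resistance integral.

    Independent numerical check of the closed-form resistance; exposed so
    analyses can report the agreement, and used directly by the tests.
    """
    w = profile.width_um * 1e-6

    def integrand(x_um: float) -> float:
        return 1.0 / (height_at(profile, x_um) * 1e-6) ** 3

    val, _ = integrate.quad(
        integrand, 0.0, profile.length_um, epsabs=0.0, epsrel=1e-12, limit=200
    )
    return 12.0 * viscosity_pa_s * (val * 1e-6) / w


def design_check(profile: ChannelProfile) -> list[str]:
    """Design-rule violations for a channel geometry.

    The one empirical rule encoded here: the outlet height must be
    >= 1.5 µm, otherwise the flow rate through the nearly-closed outlet is
    so low that detection bands take far longer than 15 min to form and
    beads aggregate or adsorb onto the channel walls.
    """
    violations: list[str] = []
    if profile.outlet_um < MIN_OUTLET_HEIGHT_UM:
        violations.append(
            f"outlet height {profile.outlet_um} µm < {MIN_OUTLET_HEIGHT_UM} µm: "
            "flow through the outlet will be too slow for detection bands to "
            "form promptly and beads risk aggregating/adsorbing to the walls"
        )
    return violations
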