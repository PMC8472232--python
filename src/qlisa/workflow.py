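"""End-to-end experiment drivers: simulate -> quantify -> statistics.

These functions tie the generative model, the masked RFU/Bead-Area
quantification and the assay statistics together into the experiments an
assay developer actually runs:

* :func:`run_standard_curve_experiment` — a full calibration run for one
  analyte (calibrator series x replicates + blanks), quantified per
  measurement; returns a tidy replicate-level table.
* :func:`analyze_standard_curve` — curve fit, LOD and intra-assay CV from
  that table, plus back-calculated concentrations.
* :func:`run_multiplex_experiment` — a multi-band sample with controls,
  quantified band by band.
* :func:`crossover_false_positive_test` — the false-positive check: an
  analyte at 0 pg/mL with and without a second analyte present, compared
  by a two-tailed t-test across fields of view.
* :func:`run_end_to_end` — the whole pipeline plus device feasibility,
  written out as a reproducible report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as qstats
from .device import ChannelProfile, TrapStatus, plan_layout
from .quantify import measure_band
from .simulate import (
    DEFAULT_CALIBRATORS,
    DEFAULT_N_BLANKS,
    SimConfig,
    default_single_plex_config,
    default_two_plex_config,
    render_fov,
    simulate_multiplex_run,
    simulate_standard_curve_run,
    _sub_seed,
)

logger = logging.getLogger("qlisa")

__all__ = [
    "RunConfig",
    "run_standard_curve_experiment",
    "analyze_standard_curve",
    "run_multiplex_experiment",
    "crossover_false_positive_test",
    "run_end_to_end",
]

#: Channel geometry used for the two-bead multiplex experiments
#: (inlet 7.583 µm, outlet 2.077 µm, 2 cm x 3 mm).
TWO_PLEX_PROFILE = ChannelProfile(20000.0, 3000.0, 7.583, 2.077)
#: Geometry used for the three-bead multiplex (inlet 6.342, outlet 0.963 µm).
THREE_PLEX_PROFILE = ChannelProfile(20000.0, 3000.0, 6.342, 0.963)


def run_standard_curve_experiment(
    config: SimConfig | None = None,
    concentrations: Sequence[float] = DEFAULT_CALIBRATORS,
    replicates: int = 3,
    n_blanks: int = DEFAULT_N_BLANKS,
    analyte: str | None = None,
    **quant_kwargs,
) -> pd.DataFrame:
    """Simulate and quantify a calibration run, one measurement at a time.

    Returns a tidy table with one row per concentration x replicate (and
    per blank), carrying the measured own-channel RFU/Bead-Area, its
    between-FOV SEM, and the generator's true (noiseless) band value.
    """
    if config is None:
        config = default_single_plex_config()
    if analyte is None:
        analyte = config.bead_specs[0].label
    channel = config.spec_for(analyte).fluor_channel

    rows = []
    for meas in simulate_standard_curve_run(
        concentrations, replicates, config, analyte=analyte, n_blanks=n_blanks
    ):
        bm = measure_band(meas.fovs, **quant_kwargs)
        true_value = float(
            np.mean([t.true_rfu_per_bead_area[channel] for t in meas.truths])
        )
        rows.append(
            {
                "analyte": analyte,
                "channel": channel,
                "concentration": meas.concentration,
                "replicate": meas.replicate,
                "is_blank": meas.is_blank,
                "rfu_per_bead_area": bm.mean[channel],
                "sem": bm.sem[channel],
                "n_fov": bm.n_fov,
                "true_rfu_per_bead_area": true_value,
            }
        )
        logger.debug(
            "measured %s c=%g rep=%d blank=%s -> %.2f",
            analyte,
            meas.concentration,
            meas.replicate,
            meas.is_blank,
            bm.mean[channel],
        )
    return pd.DataFrame(rows)


@dataclass
class CurveAnalysis:
    curve: qstats.StandardCurve
    lod: qstats.LodResult
    calibrators: pd.DataFrame  # per-concentration mean/sem
    recovery: pd.DataFrame  # per-concentration back-calculated vs spiked
    intra_assay_cv: dict[float, float]  # concentration -> CV


def analyze_standard_curve(
    table: pd.DataFrame, model: str = "four_parameter_logistic"
) -> CurveAnalysis:
    """Fit the curve, estimate LOD and CVs from a calibration-run table."""
    cal = table[~table.is_blank]
    grouped = (
        cal.groupby("concentration")["rfu_per_bead_area"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    curve = qstats.fit_standard_curve(
        grouped["concentration"], grouped["mean"], model=model, sems=grouped["sem"]
    )
    blanks = table[table.is_blank]["rfu_per_bead_area"].to_numpy()
    lod_result = qstats.lod(blanks, curve) if blanks.size >= 2 else None

    recov_rows = []
    for conc, grp in cal.groupby("concentration"):
        if conc == 0:
            continue
        inv = qstats.inverse_concentration(
            curve, float(grp["rfu_per_bead_area"].mean())
        )
        recov_rows.append(
            {
                "spiked": float(conc),
                "recovered": inv.concentration,
                "status": inv.status.value,
                "relative_error": (
                    (inv.concentration - conc) / conc
                    if inv.status is qstats.RangeStatus.OK
                    else np.nan
                ),
            }
        )
    recovery = pd.DataFrame(recov_rows)

    cvs = {
        float(conc): qstats.intra_assay_cv(grp["rfu_per_bead_area"])
        for conc, grp in cal.groupby("concentration")
        if len(grp) >= 2 and grp["rfu_per_bead_area"].mean() != 0
    }
    return CurveAnalysis(curve, lod_result, grouped, recovery, cvs)


def run_multiplex_experiment(
    sample: Mapping[str, float],
    config: SimConfig | None = None,
    profile: ChannelProfile | None = None,
    n_fov: int | None = None,
    **quant_kwargs,
) -> pd.DataFrame:
    """Simulate and quantify a multiplex sample band by band.

    Checks layout feasibility on ``profile`` first (raising on duplicate
    diameters or untrapped beads), then measures every band with its
    0 pg/mL control subtracted.  Returns one row per band x channel.
    """
    if config is None:
        config = default_two_plex_config()
    if profile is None:
        profile = TWO_PLEX_PROFILE
    layout = plan_layout(profile, config.bead_specs)
    untrapped = [
        p.bead.label for p in layout.placements if p.status is not TrapStatus.TRAPPED
    ]
    if untrapped:
        raise ValueError(
            f"layout infeasible on this channel: {untrapped} do not trap"
        )
    positions = {
        p.bead.label: p.position_um for p in layout.placements
    }

    rows = []
    for band, meas, control in simulate_multiplex_run(
        sample, config, with_controls=True, n_fov=n_fov
    ):
        bm = measure_band(meas.fovs, control.fovs, **quant_kwargs)
        for ch in bm.channels:
            rows.append(
                {
                    "band": band,
                    "band_position_um": positions[band],
                    "channel": ch,
                    "own_channel": ch == config.spec_for(band).fluor_channel,
                    "rfu_per_bead_area": bm.mean[ch],
                    "sem": bm.sem[ch],
                    "control_subtracted": bm.control_subtracted[ch],
                    "n_fov": bm.n_fov,
                    "concentration": float(sample[band]),
                }
            )
    return pd.DataFrame(rows).sort_values("band_position_um", ignore_index=True)


def crossover_false_positive_test(
    config: SimConfig | None = None,
    analyte_a: str = "IL-6",
    analyte_b: str = "GFAP",
    conc_b: float = 10000.0,
    n_fov: int = 6,
    **quant_kwargs,
) -> dict:
    """Does carryover of analyte-B beads fake a signal in A's empty band?

    Renders analyte A's detection band with A at 0 pg/mL twice: once with
    analyte B present upstream at ``conc_b`` (carryover beads carry real B
    signal) and once with everything blank.  The per-FOV own-channel
    RFU/Bead-Area values of the two conditions are compared with a
    two-tailed t-test; a non-significant p indicates the carryover does
    not generate a false positive.
    """
    if config is None:
        config = default_two_plex_config()
    channel = config.spec_for(analyte_a).fluor_channel
    blank = {b.label: 0.0 for b in config.bead_specs}
    with_b = dict(blank, **{analyte_b: conc_b})

    def band_values(concs: Mapping[str, float], tag: int) -> list[float]:
        values = []
        for k in range(n_fov):
            rng = _sub_seed(config.seed, 5, tag, k)
            pair, _ = render_fov(config, analyte_a, concs, seed=rng, fov_index=k)
            bm = measure_band([pair], **quant_kwargs)
            values.append(bm.mean[channel])
        return values

    group_with_b = band_values(with_b, 0)
    group_blank = band_values(blank, 1)
    t, p = qstats.crossover_test(group_with_b, group_blank)
    return {
        "analyte_a": analyte_a,
        "analyte_b": analyte_b,
        "conc_b": conc_b,
        "channel": channel,
        "n_fov": n_fov,
        "values_with_b": group_with_b,
        "values_blank": group_blank,
        "t": t,
        "p": p,
        "significant_at_0.05": p < 0.05,
    }


# ----------------------------------------------------------------------
# full pipeline


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    seed: int = 0
    out_dir: str | Path = "qlisa_run"
    profile: ChannelProfile = field(default_factory=lambda: TWO_PLEX_PROFILE)
    sample: dict[str, float] = field(
        default_factory=lambda: {"IL-6": 25000.0, "GFAP": 10000.0}
    )
    curve_analyte: str = "GFAP"
    calibrators: tuple[float, ...] = DEFAULT_CALIBRATORS
    replicates: int = 3
    n_blanks: int = DEFAULT_N_BLANKS
    image_shape: tuple[int, int] = (1100, 1344)
    n_fov: int = 3
    beads_per_fov: int = 200

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "profile": self.profile.to_json(),
                "sample": self.sample,
                "curve_analyte": self.curve_analyte,
                "calibrators": list(self.calibrators),
                "replicates": self.replicates,
                "n_blanks": self.n_blanks,
                "image_shape": list(self.image_shape),
                "n_fov": self.n_fov,
                "beads_per_fov": self.beads_per_fov,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_end_to_end(config: RunConfig) -> dict:
    """Simulate, quantify and analyze a full run; write a JSON report.

    Stages: device feasibility for the panel -> single-analyte standard
    curve (fit, LOD, CVs) -> multiplex sample with control subtraction ->
    per-analyte concentration "barcode".  Deterministic under the seed;
    the report carries the seed and a configuration hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    sim = default_two_plex_config(
        seed=config.seed,
        image_shape=config.image_shape,
        n_fov=config.n_fov,
        beads_per_fov=config.beads_per_fov,
    )

    logger.info("stage 1/4: device feasibility")
    layout = plan_layout(config.profile, sim.bead_specs)
    report["device"] = {
        "feasible": layout.feasible,
        "violations": layout.violations,
        "bands": [
            {
                "analyte": p.bead.label,
                "diameter_um": p.bead.diameter_mean,
                "status": p.status.value,
                "position_um": p.position_um,
            }
            for p in layout.placements
        ],
    }
    if not layout.feasible:
        # feasibility failure is a result, not a crash: report which
        # analytes fail and skip the multiplex stages
        report["device"]["note"] = "panel infeasible on this channel"
        report["barcode"] = []
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    logger.info("stage 2/4: standard curve for %s", config.curve_analyte)
    curve_cfg = default_single_plex_config(
        seed=config.seed,
        image_shape=config.image_shape,
        n_fov=config.n_fov,
        beads_per_fov=config.beads_per_fov,
    )
    table = run_standard_curve_experiment(
        curve_cfg,
        concentrations=config.calibrators,
        replicates=config.replicates,
        n_blanks=config.n_blanks,
    )
    table.to_csv(out / "standard_curve_measurements.csv", index=False)
    analysis = analyze_standard_curve(table)
    report["standard_curve"] = {
        "analyte": config.curve_analyte,
        "model": analysis.curve.model,
        "params": analysis.curve.params,
        "residual_sd": analysis.curve.residual_sd,
        "lod_signal": analysis.lod.signal_lod,
        "lod_concentration_pg_ml": analysis.lod.concentration_lod,
        "intra_assay_cv": analysis.intra_assay_cv,
        "recovery": analysis.recovery.to_dict("records"),
    }

    logger.info("stage 3/4: multiplex sample %s", config.sample)
    mtx = run_multiplex_experiment(
        config.sample, sim, config.profile, n_fov=config.n_fov
    )
    mtx.to_csv(out / "multiplex_band_measurements.csv", index=False)

    logger.info("stage 4/4: concentration barcode")
    barcode = []
    for band, grp in mtx.groupby("band", sort=False):
        own = grp[grp.own_channel].iloc[0]
        inv = qstats.inverse_concentration(
            analysis.curve, float(own["rfu_per_bead_area"])
        ) if band == config.curve_analyte else None
        barcode.append(
            {
                "analyte": band,
                "band_position_um": float(own["band_position_um"]),
                "own_channel": own["channel"],
                "rfu_per_bead_area": float(own["rfu_per_bead_area"]),
                "control_subtracted": float(own["control_subtracted"]),
                "estimated_concentration_pg_ml": (
                    inv.concentration if inv is not None else None
                ),
            }
        )
    report["barcode"] = barcode

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
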