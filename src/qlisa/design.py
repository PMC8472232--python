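"""Reagent stoichiometry for adding a new analyte to the bead panel.

Every assay in the panel is built from the same fixed molar-ratio chain,
anchored to the largest analyte amount the assay must quantify:

* capture antibody  = 5x the maximum analyte moles,
* detection antibody = 10x the maximum analyte moles,
* quantum dot        = 2x the detection-antibody moles.

Given the analyte's molar mass, the maximum concentration and sample
volume, and the reagent stock concentrations, this module computes the
moles and pipetting volumes of each reagent.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AssayRecipe", "design_recipe", "CAPTURE_EXCESS", "DETECTION_EXCESS", "QDOT_EXCESS"]

CAPTURE_EXCESS = 5.0  # capture antibody moles per analyte mole
DETECTION_EXCESS = 10.0  # detection antibody moles per analyte mole
QDOT_EXCESS = 2.0  # quantum dot moles per detection-antibody mole

#: Assumed antibody molar mass (g/mol) when none is supplied — whole IgG.
DEFAULT_ANTIBODY_MW = 150_000.0


@dataclass
class AssayRecipe:
    analyte: str
    max_concentration_pg_ml: float
    sample_volume_ul: float
    analyte_mw: float
    analyte_moles: float
    capture_moles: float
    detection_moles: float
    qdot_moles: float
    capture_volume_ul: float | None = None
    detection_volume_ul: float | None = None
    qdot_volume_ul: float | None = None
    antibody_mw_assumed: bool = False

    def as_table(self) -> str:
        lines = [
            f"Assay recipe for {self.analyte} "
            f"(up to {self.max_concentration_pg_ml:g} pg/mL in "
            f"{self.sample_volume_ul:g} µL)",
            f"  analyte:            {self.analyte_moles:.3e} mol",
            f"  capture antibody:   {self.capture_moles:.3e} mol (5x)",
            f"  detection antibody: {self.detection_moles:.3e} mol (10x)",
            f"  quantum dots:       {self.qdot_moles:.3e} mol (2x detection)",
        ]
        for name, vol in (
            ("capture", self.capture_volume_ul),
            ("detection", self.detection_volume_ul),
            ("quantum dot", self.qdot_volume_ul),
        ):
            if vol is not None:
                lines.append(f"  {name} volume: {vol:.4g} µL")
        if self.antibody_mw_assumed:
            lines.append("  note: antibody molar mass assumed 150 kDa (IgG)")
        return "\n".join(lines)


def design_recipe(
    analyte: str,
    max_concentration_pg_ml: float,
    sample_volume_ul: float,
    analyte_mw: float,
    capture_stock_mg_ml: float | None = None,
    capture_mw: float | None = None,
    detection_stock_mg_ml: float | None = None,
    detection_mw: float | None = None,
    qdot_stock_um: float | None = None,
) -> AssayRecipe:
    """Compute reagent moles and volumes from the fixed ratio chain.

    Analyte moles = max_concentration x sample_volume / molar mass.
    Antibody volumes are computed from mg/mL stocks via the antibody molar
    mass (assumed 150 kDa IgG when not given); quantum-dot volume from a
    µM stock.
    """
    if min(max_concentration_pg_ml, sample_volume_ul, analyte_mw) <= 0:
        raise ValueError("concentration, volume and molar mass must be positive")

    grams = max_concentration_pg_ml * 1e-12 * sample_volume_ul * 1e-3  # pg/mL * mL
    analyte_moles = grams / analyte_mw
    capture_moles = CAPTURE_EXCESS * analyte_moles
    detection_moles = DETECTION_EXCESS * analyte_moles
    qdot_moles = QDOT_EXCESS * detection_moles

    mw_assumed = False

    def antibody_volume(moles: float, stock_mg_ml: float | None, mw: float | None):
        nonlocal mw_assumed
        if stock_mg_ml is None:
            return None
        if stock_mg_ml <= 0:
            raise ValueError("stock concentration must be positive")
        if mw is None:
            mw = DEFAULT_ANTIBODY_MW
            mw_assumed = True
        return moles * mw / (stock_mg_ml * 1e-3) * 1e6  # g / (g/mL) -> mL -> µL

    capture_vol = antibody_volume(capture_moles, capture_stock_mg_ml, capture_mw)
    detection_vol = antibody_volume(detection_moles, detection_stock_mg_ml, detection_mw)
    qdot_vol = None
    if qdot_stock_um is not None:
        if qdot_stock_um <= 0:
            raise ValueError("quantum-dot stock molarity must be positive")
        qdot_vol = qdot_moles / (qdot_stock_um * 1e-6) * 1e6  # mol/(mol/L) -> L -> µL

    return AssayRecipe(
        analyte=analyte,
        max_concentration_pg_ml=max_concentration_pg_ml,
        sample_volume_ul=sample_volume_ul,
        analyte_mw=analyte_mw,
        analyte_moles=analyte_moles,
        capture_moles=capture_moles,
        detection_moles=detection_moles,
        qdot_moles=qdot_moles,
        capture_volume_ul=capture_vol,
        detection_volume_ul=detection_vol,
        qdot_volume_ul=qdot_vol,
        antibody_mw_assumed=mw_assumed,
    )
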