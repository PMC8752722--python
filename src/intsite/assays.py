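"""Printed assay arithmetic: ddPCR copy number, LDH cytotoxicity, tumor volume.

ddPCR vector copy number per genome is fractional abundance of the
experimental (FAM) amplicon against the RNase P (HEX) reference, adjusted
for the two reference copies per diploid genome:

    copies/cell = 2 x target_conc / ref_conc

Copies per CAR+ cell divides by the CAR+ cell fraction; samples with 0%
CAR+ report 0 by convention (transposon-only controls). LDH percent
cytotoxicity normalises experimental release between spontaneous and
detergent-lysis maximum release; results are reported raw (they may be
negative or exceed 100). Tumor volume uses the caliper formula
length x width^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd


@dataclass
class DdpcrSample:
    target_conc: float  # copies/uL, experimental FAM assay
    ref_conc: float  # copies/uL, RNase P HEX reference
    car_pos_fraction: float  # proportion in [0, 1]

    def __post_init__(self) -> None:
        if self.ref_conc <= 0:
            raise ValueError("ref_conc must be positive")
        if not 0.0 <= self.car_pos_fraction <= 1.0:
            raise ValueError("car_pos_fraction must be in [0, 1]")


@dataclass
class CytotoxicityWells:
    experimental: float
    effector_spont: float
    target_spont: float
    target_max: float  # complete lysis (0.8% Triton X-100)

    def __post_init__(self) -> None:
        if self.target_max <= self.target_spont:
            raise ValueError(
                "target_max must exceed target_spont for a defined result"
            )


@dataclass
class TumorMeasure:
    length: float  # mm
    width: float  # mm

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")


def copies_per_cell(target_conc: float, ref_conc: float) -> float:
    """Vector copies per genome: 2 x target / reference concentration."""
    if ref_conc <= 0:
        raise ValueError("ref_conc must be positive")
    return 2.0 * target_conc / ref_conc


def copies_per_car_cell(copies_cell: float, car_pos_fraction: float) -> float:
    """Copies per CAR+ cell; 0 when the CAR+ fraction is 0.

    Negative copies/cell (over-subtracted background in no-CAR controls)
    pass through the division unclamped.
    """
    if not 0.0 <= car_pos_fraction <= 1.0:
        raise ValueError("car_pos_fraction must be in [0, 1]")
    if car_pos_fraction == 0.0:
        return 0.0
    return copies_cell / car_pos_fraction


def round_report(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for report tables (internals stay unrounded)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_cytotoxicity(wells: CytotoxicityWells) -> float:
    """LDH percent cytotoxicity.

    (experimental − effector spontaneous − target spontaneous) /
    (target maximum − target spontaneous) × 100, unclamped.
    """
    num = wells.experimental - wells.effector_spont - wells.target_spont
    den = wells.target_max - wells.target_spont
    return 100.0 * num / den


def tumor_volume(m: TumorMeasure) -> float:
    """Caliper tumor volume in mm^3: length x width^2 / 2."""
    return m.length * m.width**2 / 2.0


def ddpcr_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Copy-number report from a ddPCR sample table.

    Input columns: ``sample`` plus either raw concentrations
    (``target_conc``, ``ref_conc``) or a pre-computed ``copies_per_cell``,
    and ``car_pos_pct`` (percent). Output adds ``copies_per_cell`` and
    ``copies_per_car_cell``, rounded to 2 dp for presentation.
    """
    out = samples.copy()
    if "copies_per_cell" not in out.columns:
        out["copies_per_cell"] = [
            copies_per_cell(t, r)
            for t, r in zip(out["target_conc"], out["ref_conc"])
        ]
    out["copies_per_car_cell"] = [
        round_report(copies_per_car_cell(c, pct / 100.0))
        for c, pct in zip(out["copies_per_cell"], out["car_pos_pct"])
    ]
    out["copies_per_cell"] = [round_report(c) for c in out["copies_per_cell"]]
    return out


def ldh_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Percent-cytotoxicity column from well-wise LDH readings.

    Input columns: ``experimental``, ``effector_spont``, ``target_spont``,
    ``target_max`` (any id columns are passed through).
    """
    out = plate.copy()
    out["percent_cytotoxicity"] = [
        percent_cytotoxicity(CytotoxicityWells(e, es, ts, tm))
        for e, es, ts, tm in zip(
            out["experimental"],
            out["effector_spont"],
            out["target_spont"],
            out["target_max"],
        )
    ]
    return out
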