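"""Deterministic calculators for the colorimetric and kinetic assays.

Lactate is quantified by inverting a linear standard curve on
blank-corrected optical density; enzyme activities (pyruvate kinase and
lactate dehydrogenase via NADH oxidation at 340 nm, succinate dehydrogenase
via DCIP reduction at 600 nm) follow Beer-Lambert kinetics; everything is
normalised per 10^6 cells. The calculators are unit-agnostic: the standard
curve's concentration unit and the extinction coefficient's unit carry
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StandardCurve",
    "KineticRead",
    "NADH_EXTINCTION",
    "DCIP_EXTINCTION",
    "lactate_from_od",
    "normalize_per_million_cells",
    "enzyme_activity",
    "metabolite_ratio",
]

#: Millimolar extinction coefficients, as conventionally tabulated for these
#: assays (NADH at 340 nm; DCIP at 600 nm).
NADH_EXTINCTION = 6.3e-3
DCIP_EXTINCTION = 12.42e-3


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration OD = slope * concentration + intercept."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be nonzero")


@dataclass(frozen=True)
class KineticRead:
    """One kinetic assay read: absorbance slope plus normalisation constants."""

    delta_absorbance_per_min: float
    extinction_coefficient: float
    path_length: float = 1.0  # cm
    reaction_volume: float = 1.0  # mL
    cell_count: float = 1e6

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0:
            raise ValueError("extinction coefficient must be > 0")
        if self.path_length <= 0:
            raise ValueError("path length must be > 0")
        if self.cell_count <= 0:
            raise ValueError("cell count must be > 0")


def lactate_from_od(
    od: float, od_corrected: float, dilution_factor: float, curve: StandardCurve
) -> float:
    """Lactate concentration from blank-corrected OD via the standard curve.

    ((od - od_corrected) * dilution_factor - intercept) / slope, in the
    concentration unit of the curve.
    """
    return ((od - od_corrected) * dilution_factor - curve.intercept) / curve.slope


def normalize_per_million_cells(amount: float, cell_count: float) -> float:
    """Scale ``amount`` to a per-10^6-cells basis."""
    if cell_count <= 0:
        raise ValueError("cell count must be > 0")
    return amount / (cell_count / 1e6)


def enzyme_activity(read: KineticRead) -> float:
    """Enzymatic activity from an absorbance-rate read, per 10^6 cells.

    Beer-Lambert inversion: concentration rate = dA/dt / (epsilon * l); the
    activity is that rate times the reaction volume, normalised per 10^6
    cells. Units follow the extinction coefficient (a millimolar epsilon
    yields mmol-scale substrate turnover per minute, i.e. the mIU
    convention used with these assays).
    """
    rate = read.delta_absorbance_per_min / (
        read.extinction_coefficient * read.path_length
    )
    return normalize_per_million_cells(rate * read.reaction_volume, read.cell_count)


def metabolite_ratio(numerator: float, denominator: float) -> float:
    """Dimensionless metabolite ratio (NAD+/NADH, NADP+/NADPH, ATP/ADP...)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return numerator / denominator
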