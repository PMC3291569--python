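"""Relative DnaA quantification and per-origin accounting.

Immunoblot band intensities (DnaA, with FtsZ as loading control) are
normalized either to culture optical density — giving relative DnaA
*concentration* — or to cell number — giving relative DnaA *per cell*.
Dividing an absolute per-cell estimate by the measured mean origins per cell
gives DnaA per origin, the quantity initiation models care about.
Hemocytometer counts at matched optical density give relative cell mass:
more cells at equal OD means smaller cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError

__all__ = [
    "NormalizationBasis",
    "BlotMeasurement",
    "CountMeasurement",
    "relative_dnaa_level",
    "dnaa_per_ori",
    "relative_mass_per_cell",
]


class NormalizationBasis(str, Enum):
    OPTICAL_DENSITY = "optical_density"
    CELL_COUNT = "cell_count"


@dataclass(frozen=True)
class BlotMeasurement:
    """One immunoblot lane: band and loading-control intensities plus the
    quantity gel loading was normalized to (OD600 or cells/mL)."""

    band_intensity: float
    loading_control_intensity: float
    normalization_basis: NormalizationBasis
    basis_value: float

    def __post_init__(self) -> None:
        if self.band_intensity < 0 or self.loading_control_intensity < 0:
            raise ValidationError("intensities must be non-negative")
        if self.basis_value <= 0:
            raise ValidationError("basis_value must be positive")


@dataclass(frozen=True)
class CountMeasurement:
    """Hemocytometer cell count with the optical density it was taken at."""

    cells_per_ml: float
    od: float

    def __post_init__(self) -> None:
        if self.cells_per_ml <= 0 or self.od <= 0:
            raise ValidationError("cells_per_ml and od must be positive")


def relative_dnaa_level(test: BlotMeasurement, reference: BlotMeasurement) -> float:
    """Loading-control-corrected DnaA level of ``test`` relative to
    ``reference``: ``(band/control)_test / (band/control)_ref``.

    Both lanes must share the same normalization basis (OD-normalized lanes
    compare concentrations; count-normalized lanes compare per-cell amounts).
    """
    if test.normalization_basis != reference.normalization_basis:
        raise ValidationError(
            "cannot compare lanes normalized to different bases: "
            f"{test.normalization_basis.value} vs {reference.normalization_basis.value}"
        )
    if reference.band_intensity == 0:
        raise ValidationError("reference band intensity is zero; ratio undefined")
    if test.loading_control_intensity == 0 or reference.loading_control_intensity == 0:
        raise ValidationError("loading-control intensity is zero; ratio undefined")
    return (test.band_intensity / test.loading_control_intensity) / (
        reference.band_intensity / reference.loading_control_intensity
    )


def dnaa_per_ori(dnaa_per_cell: float, origins: float) -> float:
    """DnaA molecules per origin.

    ``dnaa_per_cell`` is an absolute molecules-per-cell estimate — a relative
    blot level scaled by a literature baseline the caller supplies (the
    baseline is experiment-specific and never assumed here).
    """
    if origins < 1:
        raise ValidationError(f"mean origins per cell must be >= 1, got {origins}")
    return dnaa_per_cell / origins


def relative_mass_per_cell(
    reference: CountMeasurement, test: CountMeasurement, *, od_tolerance: float = 0.05
) -> float:
    """Relative cell mass of ``test`` vs ``reference`` from hemocytometer
    counts at matched optical density: ``ref.cells_per_ml / test.cells_per_ml``.

    At equal OD, total biomass is equal, so more cells per mL means less mass
    per cell.  Counts taken at ODs differing by more than ``od_tolerance``
    (relative) are not comparable and raise.
    """
    if abs(test.od - reference.od) > od_tolerance * reference.od:
        raise ValidationError(
            f"optical densities differ by more than {od_tolerance:.0%}: "
            f"{reference.od} vs {test.od}; counts are not mass-comparable"
        )
    return reference.cells_per_ml / test.cells_per_ml
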