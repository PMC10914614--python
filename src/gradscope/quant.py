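"""Absolute quantitation arithmetic.

Three small, exact computations used to put molecule numbers on gel and
absorbance measurements:

* **ribosomes per cell** — Beer–Lambert on an A260 reading of purified
  70S ribosomes (molar extinction coefficient 3.84 × 10^7 M⁻¹ cm⁻¹),
  converted to molecules via Avogadro's number and divided by the number
  of lysed cells;
* **cells loaded per lane** — CFU/mL × culture volume × lane fraction;
* **copies per cell** — a western-blot sample signal divided by the slope
  of a purified-protein standard curve (least squares through the origin:
  zero protein must give zero signal) and by the cells loaded.

All three are homogeneous of degree 1 in their signal/amount inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCurveError, ParameterError

AVOGADRO = 6.02214076e23  # SI-exact, mol^-1
RIBOSOME_EXTINCTION = 3.84e7  # 70S molar extinction at 260 nm, M^-1 cm^-1


@dataclass
class StandardCurve:
    """Signal-vs-molecules calibration from a purified-protein dilution.

    ``points`` are (molecules_loaded, signal) pairs; the slope (signal per
    molecule) is fit by least squares through the origin, and residuals
    are kept so nonlinear blots can be rejected.
    """

    points: list[tuple[float, float]]
    slope: float = field(init=False)
    residuals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ParameterError("standard curve needs at least one point")
        x = np.array([p[0] for p in self.points], dtype=float)
        y = np.array([p[1] for p in self.points], dtype=float)
        if np.any(x <= 0) or np.any(y < 0):
            raise ParameterError(
                "standard points need molecules > 0 and signal >= 0"
            )
        self.slope = float((x * y).sum() / (x * x).sum())
        if self.slope <= 0:
            raise DegenerateCurveError(
                f"standard-curve slope {self.slope} is not positive"
            )
        self.residuals = y - self.slope * x


def ribosomes_per_cell(
    a260: float,
    volume_l: float,
    n_cells: float,
    epsilon: float = RIBOSOME_EXTINCTION,
    path_cm: float = 1.0,
) -> float:
    """Ribosome copies per cell from an A260 reading of a lysate volume.

    ``(a260 / (epsilon * path_cm)) * volume_l * N_A / n_cells`` —
    absorbance → molarity → moles → molecules → per cell. ``volume_l`` is
    in litres.
    """
    for name, v in (
        ("a260", a260),
        ("volume_l", volume_l),
        ("n_cells", n_cells),
        ("epsilon", epsilon),
        ("path_cm", path_cm),
    ):
        if not v > 0:
            raise ParameterError(f"{name} must be > 0; got {v}")
    molar = a260 / (epsilon * path_cm)
    return molar * volume_l * AVOGADRO / n_cells


def cells_loaded(
    cfu_per_ml: float, culture_ml: float, lane_fraction: float
) -> float:
    """Number of cells loaded per lane: CFU/mL × mL × lane fraction."""
    for name, v in (
        ("cfu_per_ml", cfu_per_ml),
        ("culture_ml", culture_ml),
        ("lane_fraction", lane_fraction),
    ):
        if not v > 0:
            raise ParameterError(f"{name} must be > 0; got {v}")
    if lane_fraction > 1:
        raise ParameterError(
            f"lane_fraction must be <= 1; got {lane_fraction}"
        )
    return cfu_per_ml * culture_ml * lane_fraction


def copies_per_cell(
    sample_signal: float, curve: StandardCurve, n_cells: float
) -> float:
    """Protein copies per cell from a blot signal and a standard curve."""
    if sample_signal < 0:
        raise ParameterError("sample_signal must be >= 0")
    if not n_cells > 0:
        raise ParameterError("n_cells must be > 0")
    if curve.slope <= 0:
        raise DegenerateCurveError("standard-curve slope is not positive")
    return (sample_signal / curve.slope) / n_cells
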