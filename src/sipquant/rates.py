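"""Carbon assimilation rates from single-cell ¹³C atom fractions, and
¹³CO₂ mineralization time-series summaries.

The rate model is a linear two-pool mass balance. A cell that assembled the
fraction ``x`` of its carbon from a substrate with ¹³C atom fraction ``K_S``
(the rest being pre-existing biomass at natural abundance ``K_NA``) shows a
measured atom fraction

    K_A = x · K_S + (1 − x) · K_NA   ⇒   x = (K_A − K_NA) / (K_S − K_NA).

With a cell biovolume ``V`` (from the region of interest) and a carbon
density ``ρ_C`` (default 93.4 fg μm⁻³, a Proteobacteria average), the cell's
carbon content is m_C = ρ_C·V and its assimilation rate over the incubation
time ``t`` is

    F_c = x · m_C / t      [fg cell⁻¹ h⁻¹].

Instrument-specific correction factors are deliberately not modeled; the
formula is isolated here so an alternative correction model can be swapped
in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .constants import NATURAL_13C
from .nanosims import CellROI

__all__ = [
    "RateParams",
    "ShapeModel",
    "CellGeometry",
    "AssimilationResult",
    "cell_volume",
    "assimilated_fraction",
    "assimilation_rate",
    "mineralization_excess",
]

#: average Proteobacteria carbon density, fg per um^3
DEFAULT_RHO_C = 93.4


@dataclass(frozen=True)
class RateParams:
    """Mass-balance parameters for one incubation.

    ``k_s`` — substrate ¹³C atom fraction (0.10 for the nanoSIMS microcosms,
    0.20 for protein-SIP); ``k_na`` — natural ¹³C atom fraction;
    ``rho_c`` — cellular carbon density, fg μm⁻³; ``t_h`` — incubation
    time, hours.
    """

    k_s: float
    t_h: float
    k_na: float = NATURAL_13C
    rho_c: float = DEFAULT_RHO_C

    def __post_init__(self) -> None:
        if self.k_s <= self.k_na:
            raise ValueError("substrate labeling k_s must exceed k_na")
        if self.rho_c <= 0:
            raise ValueError("carbon density must be positive")
        if self.t_h <= 0:
            raise ValueError("incubation time must be positive")


class ShapeModel(str, Enum):
    EQUIVALENT_SPHERE = "equivalent-sphere"
    SPHEROCYLINDER = "spherocylinder"


@dataclass(frozen=True)
class CellGeometry:
    """Biovolume of one cell derived from its 2-D region of interest."""

    area_px: int
    pixel_size_um: float
    volume_um3: float
    shape_model: ShapeModel
    low_confidence: bool = False


@dataclass(frozen=True)
class AssimilationResult:
    """Per-cell carbon assimilation: fraction, content, and rate."""

    assimilated_fraction: float
    carbon_content_fg: float
    f_c: float  # fg cell^-1 h^-1


def cell_volume(
    roi: CellROI,
    pixel_size_um: float,
    model: ShapeModel = ShapeModel.EQUIVALENT_SPHERE,
) -> CellGeometry:
    """Biovolume from a 2-D ROI.

    Equivalent-sphere (default): the circle of equal projected area defines
    the radius, V = (4/3)πr³. Spherocylinder: a cylinder of length (l − w)
    capped by hemispheres, with width ``w`` and length ``l`` taken from the
    ROI's second moments (minor/major axis of the equal-moment ellipse).
    One-pixel ROIs are computed but flagged low-confidence.
    """
    area_px = roi.area_px
    if area_px <= 0:
        raise ValueError("ROI area must be positive")
    area_um2 = area_px * pixel_size_um**2
    if model is ShapeModel.EQUIVALENT_SPHERE:
        r = math.sqrt(area_um2 / math.pi)
        volume = 4.0 / 3.0 * math.pi * r**3
    else:
        coords = np.column_stack([roi.rows, roi.cols]).astype(float)
        centered = coords - coords.mean(axis=0)
        cov = np.cov(centered.T) if area_px > 1 else np.zeros((2, 2))
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        # equal-second-moment ellipse axes (full lengths), in um
        length = 4.0 * math.sqrt(max(evals[0], 0.25)) * pixel_size_um
        width = 4.0 * math.sqrt(max(evals[1], 0.25)) * pixel_size_um
        if width > length:
            length, width = width, length
        r = width / 2.0
        volume = math.pi * r**2 * max(length - width, 0.0) + 4.0 / 3.0 * math.pi * r**3
    return CellGeometry(
        area_px=area_px,
        pixel_size_um=pixel_size_um,
        volume_um3=volume,
        shape_model=model,
        low_confidence=area_px <= 1,
    )


def assimilated_fraction(k_a: float, params: RateParams) -> float:
    """Fraction of cell carbon assimilated from the labeled substrate.

    Linear two-pool mass balance x = (K_A − K_NA)/(K_S − K_NA). Measured
    atom fractions outside [K_NA, K_S] are clamped into the physical range
    with a warning (counting noise can push K_A slightly outside it).
    """
    if not 0.0 <= k_a <= 1.0:
        raise ValueError("atom fraction K_A must lie in [0, 1]")
    if k_a < params.k_na or k_a > params.k_s:
        warnings.warn(
            f"K_A={k_a:.4g} outside [K_NA={params.k_na}, K_S={params.k_s}]; clamped"
        )
        k_a = min(max(k_a, params.k_na), params.k_s)
    return (k_a - params.k_na) / (params.k_s - params.k_na)


def assimilation_rate(
    x: float, geom: CellGeometry, params: RateParams
) -> AssimilationResult:
    """Single-cell carbon assimilation rate F_c = x·ρ_C·V / t."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("assimilated fraction x must lie in [0, 1]")
    m_c = params.rho_c * geom.volume_um3
    return AssimilationResult(
        assimilated_fraction=x,
        carbon_content_fg=m_c,
        f_c=x * m_c / params.t_h,
    )


def mineralization_excess(
    series: list[tuple[float, float]],
    background_atom_percent: float,
    measurement_sd: float = 0.05,
) -> pd.DataFrame:
    """Atom% excess of headspace ¹³CO₂ over background, with detection time.

    ``series`` is a list of (time in h, measured atom% ¹³C of CO₂) with
    non-decreasing times. Excess = measured − background; the detection flag
    marks time points whose excess exceeds 3× the stated measurement SD, so
    the first flagged row is the mineralization onset. Returns a DataFrame
    with columns time_h, atom_percent, excess, detected.
    """
    if not series:
        raise ValueError("empty time series")
    times = [t for t, _ in series]
    values = [v for _, v in series]
    if any(v < 0 for v in values) or background_atom_percent < 0:
        raise ValueError("atom% values must be non-negative")
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("time points must be non-decreasing")
    df = pd.DataFrame({"time_h": times, "atom_percent": values})
    df["excess"] = df["atom_percent"] - background_atom_percent
    df["detected"] = df["excess"] > 3.0 * measurement_sd
    if len(df) < 2:
        df["detected"] = False  # a single point cannot establish onset
    return df
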