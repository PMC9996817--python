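"""Impact and risk metrics over concentration maps and field measurements.

Reduces the dispersal model's maps and the field chemistry to the headline
risk quantities: the area and reach of water above the lethal threshold for
northern shrimp, how long concentrations stay lethal, dilution factors of
the treatment dose, active-ingredient masses of the delousing formulation,
and margins of measured sediment levels against regulatory references
(PNEC, amphipod LC50).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon, mapping
from skimage import measure as _skmeasure

from .dispersal import Grid
from .pas import Measurement

__all__ = [
    "ThresholdSet",
    "ImpactSummary",
    "SedimentSample",
    "area_above",
    "max_extent",
    "max_duration",
    "contour_polygons",
    "contours_to_geojson",
    "dilution_percent",
    "fold_dilution",
    "formulation_mass",
    "dose_scaling",
    "sediment_margin",
    "exceedance_report",
]

#: Alpha Max active-ingredient strength, g deltamethrin per litre formulation.
ALPHA_MAX_STRENGTH = 10.0


@dataclass(frozen=True)
class ThresholdSet:
    """Reference concentrations for classification and contouring."""

    lethal_water: float = 2.0  # ng L^-1, lethal to shrimp in the lab assay
    contour_high: float = 200.0  # ng L^-1, inner plume contour
    treatment: float = 2000.0  # ng L^-1, nominal treatment dose
    sediment_pnec: float = 0.33  # ng g^-1 dw, SEPA screening threshold
    sediment_lc50: float = 16.0  # ng g^-1 dw, 10-day amphipod LC50

    def __post_init__(self):
        if min(
            self.lethal_water,
            self.contour_high,
            self.treatment,
            self.sediment_pnec,
            self.sediment_lc50,
        ) < 0:
            raise ValueError("thresholds must be non-negative")
        if not self.lethal_water < self.contour_high < self.treatment:
            raise ValueError(
                "expected lethal_water < contour_high < treatment, got "
                f"{self.lethal_water}, {self.contour_high}, {self.treatment}"
            )


@dataclass(frozen=True)
class ImpactSummary:
    """Footprint of one threshold on one map."""

    threshold: float  # ng L^-1
    area_above: float  # km^2
    max_extent: float  # km from the release point
    max_duration: float  # h above threshold, worst cell

    def __post_init__(self):
        if self.area_above < 0 or self.max_extent < 0:
            raise ValueError("area and extent must be non-negative")


@dataclass(frozen=True)
class SedimentSample:
    """One grab-sample concentration, possibly censored at its LOD."""

    station: str
    distance: float  # m from the pens
    depth: float  # m water depth
    concentration: Measurement  # ng g^-1 dw

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def area_above(map2d: np.ndarray, threshold: float, cell_area: float) -> float:
    """km^2 of cells strictly exceeding a threshold (full-cell counting)."""
    if cell_area <= 0:
        raise ValueError(f"cell_area must be positive, got {cell_area}")
    map2d = np.asarray(map2d)
    return float((map2d > threshold).sum()) * cell_area / 1e6


def max_extent(
    map2d: np.ndarray, threshold: float, origin: tuple[float, float], grid: Grid
) -> float:
    """km from origin to the farthest cell centre above the threshold; 0 if none."""
    map2d = np.asarray(map2d)
    if map2d.shape != (grid.ny, grid.nx):
        raise ValueError(
            f"map shape {map2d.shape} does not match grid ({grid.ny}, {grid.nx})"
        )
    grid.index_of(origin)  # origin must lie on the grid
    mask = map2d > threshold
    if not mask.any():
        return 0.0
    xs, ys = np.meshgrid(grid.x, grid.y)
    d = np.hypot(xs[mask] - origin[0], ys[mask] - origin[1])
    return float(d.max()) / 1000.0


def max_duration(time_above_map: np.ndarray) -> float:
    """Worst-cell accumulated exposure time (h)."""
    time_above_map = np.asarray(time_above_map)
    if time_above_map.size == 0:
        raise ValueError("empty exposure-time map")
    return float(time_above_map.max())


def contour_polygons(
    map2d: np.ndarray, threshold: float, grid: Grid
) -> list[Polygon]:
    """Marching-squares isolines of the threshold, as shapely polygons.

    The field is padded with a sub-threshold rim so plumes touching the
    domain edge still close into polygons.  Polygon areas approximate
    :func:`area_above` to within a cell-ring of the contour perimeter.
    """
    map2d = np.asarray(map2d, dtype=float)
    if not np.isfinite(map2d).all():
        raise ValueError("concentration map contains NaN or inf")
    pad_value = min(map2d.min(), threshold) - max(abs(threshold), 1.0)
    padded = np.pad(map2d, 1, constant_values=pad_value)
    contours = _skmeasure.find_contours(padded, threshold)
    polys = []
    for contour in contours:
        if len(contour) < 4:
            continue
        # (row, col) in padded index space -> metres at cell centres
        ys = grid.origin[1] + (contour[:, 0] - 1 + 0.5) * grid.dx
        xs = grid.origin[0] + (contour[:, 1] - 1 + 0.5) * grid.dx
        poly = Polygon(np.column_stack([xs, ys]))
        if poly.is_valid and poly.area > 0:
            polys.append(poly)
    return polys


def contours_to_geojson(
    polys: Sequence[Polygon], threshold: float, path=None
) -> dict:
    """FeatureCollection of contour polygons; optionally written to a file."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p),
                "properties": {
                    "threshold_ng_per_L": threshold,
                    "area_km2": p.area / 1e6,
                },
            }
            for p in polys
        ],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def dilution_percent(ambient: float, treatment: float) -> float:
    """Ambient concentration as a percentage of the treatment dose."""
    if treatment <= 0:
        raise ValueError(f"treatment concentration must be positive, got {treatment}")
    return 100.0 * ambient / treatment


def fold_dilution(treatment: float, ambient: float) -> float:
    """How many times the treatment dose has been diluted to reach ambient."""
    if ambient <= 0:
        raise ValueError(f"ambient concentration must be positive, got {ambient}")
    return treatment / ambient


def formulation_mass(volume: float, strength: float = ALPHA_MAX_STRENGTH) -> float:
    """Active-ingredient mass (g) in a formulation volume (L)."""
    if volume < 0 or strength < 0:
        raise ValueError("volume and strength must be non-negative")
    return volume * strength


def dose_scaling(recommended: float, factor: float) -> float:
    """Applied dose (ng L^-1) as a multiple of the recommended dose."""
    if factor <= 0:
        raise ValueError(f"dose factor must be positive, got {factor}")
    return recommended * factor


def sediment_margin(reference: float, measured) -> tuple[float, bool]:
    """Fold by which a measurement sits below a reference level.

    Returns ``(fold, censored)``.  A censored measurement uses its LOD as
    an upper bound, so the returned fold is a *lower* bound on the true
    margin and is flagged as censored.
    """
    censored = False
    if isinstance(measured, Measurement):
        censored = measured.censored
        measured = measured.upper_bound
    if measured <= 0:
        raise ValueError(f"measured concentration must be positive, got {measured}")
    return reference / measured, censored


def exceedance_report(
    water: Iterable = (),
    sediment: Iterable[SedimentSample] = (),
    thresholds: ThresholdSet = ThresholdSet(),
) -> list[dict]:
    """Classify every record against its lethal/screening threshold.

    Water estimates are judged against the lethal concentration for shrimp,
    sediment samples against the sediment PNEC.  Classes: ``above``,
    ``within_10x_below`` (within one order of magnitude under the
    threshold), ``below``.  Censored entries are classified with the LOD as
    an upper bound and flagged.
    """

    def classify(value: float, threshold: float) -> str:
        if value > threshold:
            return "above"
        if value >= threshold / 10.0:
            return "within_10x_below"
        return "below"

    report = []
    for est in water:
        report.append(
            {
                "medium": "water",
                "id": est.label,
                "value": est.cw,
                "units": "ng L-1",
                "threshold": thresholds.lethal_water,
                "class": classify(est.cw, thresholds.lethal_water),
                "censored": False,
            }
        )
    for samp in sediment:
        m = samp.concentration
        report.append(
            {
                "medium": "sediment",
                "id": samp.station,
                "value": m.upper_bound,
                "units": "ng g-1 dw",
                "threshold": thresholds.sediment_pnec,
                "class": classify(m.upper_bound, thresholds.sediment_pnec),
                "censored": m.censored,
            }
        )
    return report
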