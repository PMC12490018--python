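"""Domain types and unit conventions for basin-scale DDX sediment analysis.

Conventions used throughout the package:

* Coordinates are planar projected meters (a local basin projection).
* Depths are cm below the sediment-water interface, positive downward;
  slice intervals are half-open ``[z_top, z_bottom)``.
* Concentrations are ug/kg dry sediment; areal inventories are mg/m^2
  over the top ``integration_depth`` cm; basin burdens are tonnes.
* ``DDX`` is always the derived sum of the six measured congeners
  (2,4'- and 4,4'- isomers of DDT, DDD and DDE); it is never an input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, MultiPolygon

logger = logging.getLogger("ddxburden")

# --------------------------------------------------------------------------
# Analytes
# --------------------------------------------------------------------------

#: The six measured congeners: parent DDT and its single-dechlorination
#: daughters DDD and DDE, each as the 2,4'- and 4,4'- structural isomer.
CONGENERS: tuple[str, ...] = (
    "ddt_24", "ddt_44",
    "ddd_24", "ddd_44",
    "dde_24", "dde_44",
)

#: Analyte groups: each parent compound sums its two isomers; DDX sums all six.
ANALYTES: dict[str, tuple[str, ...]] = {
    "ddt": ("ddt_24", "ddt_44"),
    "ddd": ("ddd_24", "ddd_44"),
    "dde": ("dde_24", "dde_44"),
    "ddx": CONGENERS,
}


def analyte_total(conc: Mapping[str, float], analyte: str) -> float:
    """Sum congener concentrations for one analyte group.

    ``analyte`` may be a congener key (returned as-is), or one of
    ``ddt``, ``ddd``, ``dde``, ``ddx``.
    """
    if analyte in CONGENERS:
        return float(conc.get(analyte, 0.0))
    try:
        keys = ANALYTES[analyte]
    except KeyError:
        raise KeyError(f"unknown analyte {analyte!r}") from None
    return float(sum(conc.get(k, 0.0) for k in keys))


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks a required column."""


# --------------------------------------------------------------------------
# Core sample types
# --------------------------------------------------------------------------

@dataclass
class Slice:
    """One horizontal core slice: ``[z_top, z_bottom)`` cm below the interface.

    ``conc`` maps congener keys to ug/kg dry weight; ``total_solids`` is the
    dry-mass fraction of the wet sediment (None if not measured, to be filled
    from neighboring slices).
    """

    z_top: float
    z_bottom: float
    conc: dict[str, float]
    total_solids: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.z_top < self.z_bottom):
            raise ValidationError(
                f"slice interval [{self.z_top}, {self.z_bottom}) is invalid"
            )
        for k, v in self.conc.items():
            if k not in CONGENERS:
                raise ValidationError(f"unknown congener column {k!r}")
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"negative or non-finite concentration {v} for {k}"
                )
        if self.total_solids is not None and not (0.0 < self.total_solids <= 1.0):
            raise ValidationError(
                f"total_solids {self.total_solids} outside (0, 1]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.z_top + self.z_bottom)

    @property
    def thickness(self) -> float:
        return self.z_bottom - self.z_top

    def analyte(self, analyte: str) -> float:
        return analyte_total(self.conc, analyte)


@dataclass
class DepthProfile:
    """Ordered, non-overlapping slices of one core. Gaps are permitted and
    are filled by interpolation at inventory time."""

    slices: list[Slice]

    def __post_init__(self) -> None:
        self.slices = sorted(self.slices, key=lambda s: s.z_top)
        for a, b in zip(self.slices, self.slices[1:]):
            if b.z_top < a.z_bottom - 1e-12:
                raise ValidationError(
                    f"overlapping slices [{a.z_top}, {a.z_bottom}) and "
                    f"[{b.z_top}, {b.z_bottom})"
                )

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def midpoints(self) -> np.ndarray:
        return np.array([s.midpoint for s in self.slices])

    def values(self, analyte: str) -> np.ndarray:
        return np.array([s.analyte(analyte) for s in self.slices])


@dataclass
class MiniCore:
    """A vertically integrated mini piston core replicate.

    ``content`` is the interval-mean concentration (ug/kg dry) per congener
    over the sampled interval, the lab-report convention for a composite.
    """

    station_id: str
    replicate: int
    interval: str  # "0-12" | "12-24"
    content: dict[str, float]
    cross_section_weight: float = 1.0

    _INTERVALS = {"0-12": (0.0, 12.0), "12-24": (12.0, 24.0)}

    def __post_init__(self) -> None:
        if self.interval not in self._INTERVALS:
            raise ValidationError(
                f"mini-core interval {self.interval!r} not one of "
                f"{sorted(self._INTERVALS)}"
            )
        if not 1 <= int(self.replicate) <= 3:
            raise ValidationError(f"replicate {self.replicate} outside 1..3")
        for k, v in self.content.items():
            if k not in CONGENERS:
                raise ValidationError(f"unknown congener column {k!r}")
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"negative mini-core content {v} for {k}")

    @property
    def z_top(self) -> float:
        return self._INTERVALS[self.interval][0]

    @property
    def z_bottom(self) -> float:
        return self._INTERVALS[self.interval][1]

    def analyte(self, analyte: str) -> float:
        return analyte_total(self.content, analyte)


@dataclass
class Station:
    """A sampling site with its depth-resolved profile and optional
    mini-core replicates.

    ``core_cross_section_ratio`` is the cross-sectional area of the sliced
    core relative to one mini piston core (~12 for the multicorer barrels
    versus the cut syringe subcores); it weights the sliced core in
    triplicate statistics.
    """

    id: str
    x: float
    y: float
    water_depth: float
    sampling_year: float
    profile: DepthProfile
    minicores: list[MiniCore] = field(default_factory=list)
    core_cross_section_ratio: float = 12.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"station {self.id}: non-finite coordinates")
        if not self.sampling_year > 1955.0:
            raise ValidationError(
                f"station {self.id}: sampling_year {self.sampling_year} "
                "must postdate the 1955 peak-DDT anchor"
            )
        if not self.core_cross_section_ratio > 0:
            raise ValidationError(
                f"station {self.id}: core_cross_section_ratio must be positive"
            )

    def minicore_replicates(self) -> dict[int, list[MiniCore]]:
        """Group mini-cores by replicate number (each replicate may sample
        one or both depth intervals)."""
        out: dict[int, list[MiniCore]] = {}
        for mc in self.minicores:
            out.setdefault(int(mc.replicate), []).append(mc)
        return out


@dataclass
class SedimentConstants:
    """Physical constants of the two-phase (grains + porewater) sediment
    model used to convert dry-weight concentrations to areal mass.

    Defaults: basin-composite grain density 2.5832 +/- 0.0049 g/cm^3,
    seawater porewater 1.025 g/cm^3, inventories over the top 30 cm.
    """

    grain_density: float = 2.5832
    grain_density_sd: float = 0.0049
    porewater_density: float = 1.025
    integration_depth: float = 30.0

    def __post_init__(self) -> None:
        for name in ("grain_density", "grain_density_sd",
                     "porewater_density", "integration_depth"):
            if not getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be non-negative")
        if not (self.grain_density > 0 and self.porewater_density > 0
                and self.integration_depth > 0):
            raise ValidationError("sediment constants must be positive")


# --------------------------------------------------------------------------
# Spatial types
# --------------------------------------------------------------------------

@dataclass
class StudyArea:
    """The basin polygon (planar meters). Area is computed from the ring
    geometry (shoelace over rings, holes subtracted), never an input."""

    polygon: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValidationError("study-area polygon is not simple "
                                  "(self-intersecting or otherwise invalid)")
        if not self.polygon.area > 0:
            raise ValidationError("study-area polygon has zero area")

    @property
    def area(self) -> float:
        """Polygon area in m^2."""
        return float(self.polygon.area)

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return shapely.contains_xy(self.polygon, x, y)


@dataclass
class Surface:
    """A regular raster of an interpolated field, ESRI-style orientation:
    ``values[0, :]`` is the northernmost row. NaN marks masked cells
    (outside the polygon or outside the station hull under the mask policy).
    """

    x_ll: float            # x of the grid's lower-left corner (m)
    y_ll: float            # y of the grid's lower-left corner (m)
    cellsize: float        # cell edge length (m)
    values: np.ndarray     # (nrows, ncols), NaN = masked

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("surface grid must be a non-empty 2-D array")
        if not self.cellsize > 0:
            raise ValidationError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cellsize ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of shape (nrows, ncols); row 0 is the north edge."""
        j = np.arange(self.ncols)
        i = np.arange(self.nrows)
        x = self.x_ll + (j + 0.5) * self.cellsize
        y = self.y_ll + (self.nrows - 1 - i + 0.5) * self.cellsize
        return np.meshgrid(x, y)[0], np.tile(y[:, None], (1, self.ncols))

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class ArealInventory:
    """Per-station, per-analyte contaminant mass per unit seabed area
    (mg/m^2) over the top ``integration_depth`` cm.

    ``fraction_by_interval`` records what proportion of the DDX inventory
    sits in 0-12 / 12-24 / 24-30 cm according to the sliced profile; it is
    the reference for scaling vertically truncated mini-core measurements.
    """

    station_id: str
    inventory: dict[str, float]          # analyte/congener -> mg/m^2
    method: str = "sliced"               # "sliced" | "minicore_scaled"
    fraction_by_interval: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for k, v in self.inventory.items():
            if v < -1e-9:
                raise ValidationError(
                    f"negative inventory {v} for {k} at {self.station_id}"
                )
        if self.fraction_by_interval is not None:
            s = sum(self.fraction_by_interval)
            if abs(s - 1.0) > 1e-6:
                raise ValidationError(
                    f"interval fractions sum to {s}, expected 1"
                )

    @property
    def ddx(self) -> float:
        return self.inventory["ddx"]


@dataclass
class BurdenEstimate:
    """A basin-scale burden: mean areal inventory (mg/m^2), the total it
    scales to (tonnes; total = mean x area_m2 x 1e-9 exactly), and the
    uncertainty sigma with the procedure that produced it."""

    mean_inventory: float
    total: float
    sigma: float
    method: str                       # "point" | "jackknife_bootstrap" | "monte_carlo"
    sigma_units: str = "tonnes"
    n: int | None = None

    @classmethod
    def from_mean(cls, mean_inventory: float, area_m2: float, sigma: float,
                  method: str, **kw) -> "BurdenEstimate":
        return cls(mean_inventory=float(mean_inventory),
                   total=float(mean_inventory) * area_m2 * 1e-9,
                   sigma=float(sigma), method=method, **kw)


MG_PER_M2_TO_TONNES = 1e-9  # per m^2 of area: mg -> tonnes
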