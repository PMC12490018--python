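"""Depth-integrated areal inventories (mg/m^2 over the top 30 cm).

The conversion from dry-weight concentration to areal mass uses a two-phase
sediment model: wet bulk density from % total solids (TS) and the grain and
porewater densities,

    rho_wet = 1 / (TS/rho_grain + (1 - TS)/rho_water)

so the dry mass per wet volume is rho_db = TS * rho_wet (g/cm^3). A 1-cm
layer with concentration C (ug/kg dry) then holds C * rho_db * dz * 0.01
mg/m^2.

Unmeasured depths are filled by linear interpolation between the midpoints
of the nearest measured slices; beyond the shallowest/deepest midpoint the
nearest measured value is extended as a constant (linear extrapolation can
go negative and is deliberately not the default).
"""

from __future__ import annotations

import logging

import numpy as np

from .model import (
    ANALYTES,
    CONGENERS,
    ArealInventory,
    DepthProfile,
    MiniCore,
    SedimentConstants,
    ValidationError,
)

logger = logging.getLogger("ddxburden")

#: Basin default dry-mass fraction used when a core has no % total solids.
DEFAULT_TOTAL_SOLIDS = 0.35


def dry_mass_per_volume(total_solids, constants: SedimentConstants | None = None):
    """Dry sediment mass per unit wet volume, g/cm^3, from the two-phase
    (grains + porewater) mixing model."""
    if constants is None:
        constants = SedimentConstants()
    ts = np.asarray(total_solids, dtype=float)
    if np.any(ts <= 0) or np.any(ts > 1):
        raise ValidationError(f"total_solids {total_solids} outside (0, 1]")
    rho_wet = 1.0 / (ts / constants.grain_density
                     + (1.0 - ts) / constants.porewater_density)
    out = ts * rho_wet
    return float(out) if out.ndim == 0 else out


def total_solids_series(profile: DepthProfile,
                        default: float = DEFAULT_TOTAL_SOLIDS) -> np.ndarray:
    """Per-slice % total solids, with missing values filled by linear
    interpolation from measured neighbors in the same core (constant at the
    ends); if the core has none at all, a basin default with a warning."""
    ts = np.array([np.nan if s.total_solids is None else s.total_solids
                   for s in profile], dtype=float)
    if np.isnan(ts).all():
        logger.warning("profile has no %% total solids; using basin default "
                       "%.2f", default)
        return np.full(len(ts), default)
    if np.isnan(ts).any():
        z = profile.midpoints()
        good = ~np.isnan(ts)
        ts[~good] = np.interp(z[~good], z[good], ts[good])
    return ts


def fill_profile(profile: DepthProfile, analyte: str,
                 grid: np.ndarray | None = None,
                 constants: SedimentConstants | None = None) -> np.ndarray:
    """Gap-free concentration series on a 1-cm depth grid.

    Values at unmeasured depths are linearly interpolated between the
    midpoints of the nearest measured slices; beyond the outermost midpoints
    the nearest measured value is extended (np.interp's clamping), clipped
    at zero. Requires >= 2 slices.
    """
    if len(profile) < 2:
        raise ValidationError(
            f"need >=2 slices to fill a profile, got {len(profile)}"
        )
    if grid is None:
        depth = (constants or SedimentConstants()).integration_depth
        grid = depth_grid(depth)
    z = profile.midpoints()
    v = profile.values(analyte)
    return np.clip(np.interp(grid, z, v), 0.0, None)


def depth_grid(integration_depth: float = 30.0, dz: float = 1.0) -> np.ndarray:
    """Centers of dz-cm layers over [0, integration_depth)."""
    n = int(round(integration_depth / dz))
    return (np.arange(n) + 0.5) * dz


def areal_inventory(profile: DepthProfile,
                    constants: SedimentConstants | None = None,
                    station_id: str = "", dz: float = 1.0) -> ArealInventory:
    """Top-``integration_depth`` areal inventory (mg/m^2) of each congener
    and analyte group, from the sliced profile.

    Inventory = sum over dz-cm layers of C(z) [ug/kg] x rho_db(z) [g/cm^3]
    x dz [cm] x 0.01. Computed per congener, then summed into DDT/DDD/DDE
    and DDX so the group inventories are exact congener sums.
    """
    constants = constants or SedimentConstants()
    grid = depth_grid(constants.integration_depth, dz)
    z_mid = profile.midpoints()
    ts_slices = total_solids_series(profile)
    if len(profile) >= 2:
        ts = np.interp(grid, z_mid, ts_slices)
    else:
        ts = np.full(grid.shape, ts_slices[0])
    rho_db = dry_mass_per_volume(ts, constants)

    inv: dict[str, float] = {}
    layer_ddx = np.zeros_like(grid)
    for c in CONGENERS:
        conc = fill_profile(profile, c, grid=grid)
        layers = conc * rho_db * dz * 0.01
        inv[c] = float(layers.sum())
        layer_ddx += layers
    for a, keys in ANALYTES.items():
        inv[a] = float(sum(inv[k] for k in keys))

    total = layer_ddx.sum()
    if total > 0:
        f = tuple(float(layer_ddx[(grid >= lo) & (grid < hi)].sum() / total)
                  for lo, hi in ((0, 12), (12, 24), (24, constants.integration_depth)))
    else:
        f = None
    return ArealInventory(station_id=station_id, inventory=inv,
                          method="sliced", fraction_by_interval=f)


def minicore_areal_content(minicore: MiniCore, profile: DepthProfile,
                           constants: SedimentConstants | None = None) -> dict[str, float]:
    """Areal mass (mg/m^2) held in the mini-core's sampled interval, per
    congener, converting its interval-mean concentration with the station's
    mean dry bulk density over that interval."""
    constants = constants or SedimentConstants()
    grid = depth_grid(constants.integration_depth)
    sel = (grid >= minicore.z_top) & (grid < minicore.z_bottom)
    z_mid = profile.midpoints()
    ts_slices = total_solids_series(profile)
    ts = np.interp(grid[sel], z_mid, ts_slices)
    rho = float(np.mean(dry_mass_per_volume(ts, constants)))
    thickness = minicore.z_bottom - minicore.z_top
    out = {c: minicore.content.get(c, 0.0) * rho * thickness * 0.01
           for c in CONGENERS}
    return out


def scale_minicore(minicores: list[MiniCore], reference: ArealInventory,
                   profile: DepthProfile,
                   constants: SedimentConstants | None = None) -> ArealInventory:
    """Scale one mini-core replicate (its 0-12 cm, and optionally 12-24 cm,
    composite) to a full top-30-cm inventory.

    The sliced core's DDX ``fraction_by_interval`` (f1, f2, f3) is the
    reference for how much of the inventory lies within the mini-core's
    reach: with only 0-12 cm sampled, inventory = content/f1; with both
    intervals, inventory = (sum of contents)/(f1 + f2).
    """
    if reference.fraction_by_interval is None:
        raise ValidationError(
            f"station {reference.station_id}: reference profile has no DDX, "
            "interval fractions undefined"
        )
    if not minicores:
        raise ValidationError("no mini-core measurements supplied")
    intervals = sorted({mc.interval for mc in minicores})
    if len(intervals) != len(minicores):
        raise ValidationError("duplicate mini-core interval within a replicate")
    f1, f2, _f3 = reference.fraction_by_interval
    covered = 0.0
    for iv in intervals:
        covered += {"0-12": f1, "12-24": f2}[iv]
    if covered <= 0:
        raise ValidationError(
            f"station {reference.station_id}: reference holds no DDX mass in "
            f"the sampled interval(s) {intervals}; cannot scale mini-core"
        )
    content: dict[str, float] = {c: 0.0 for c in CONGENERS}
    for mc in minicores:
        areal = minicore_areal_content(mc, profile, constants)
        for c in CONGENERS:
            content[c] += areal[c]
    inv = {c: content[c] / covered for c in CONGENERS}
    for a, keys in ANALYTES.items():
        inv[a] = float(sum(inv[k] for k in keys))
    return ArealInventory(station_id=minicores[0].station_id, inventory=inv,
                          method="minicore_scaled",
                          fraction_by_interval=reference.fraction_by_interval)
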