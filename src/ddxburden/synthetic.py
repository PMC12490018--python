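"""Synthetic basin generator with known ground truth.

Emulates the statistical structure the burden analysis assumes, so every
stage of the pipeline is testable end-to-end without field data:

* a NE-SW band of high DDT (and proportional DDD) concentration across the
  basin, with a localized hotspot exceeding 50,000 ug/kg at its western
  periphery (one station is snapped onto the hotspot so the maximum is
  actually sampled, as a survey targeting a known dumpsite would);
* a DDE field with the same band plus a gradient decaying away from the
  northern shelf edge, and a surface tail of recent DDE deposition;
* depth profiles peaking at 5-9 cm (Gaussian in depth for DDT/DDD, broader
  for DDE), sliced at 2-cm resolution;
* multiplicative lognormal "patchiness" noise: one mean-preserving patch
  factor per core (or mini-core replicate) per analyte at the configured
  CV (56.5% for DDT/DDD, 20% for DDE), plus a smaller per-slice jitter, so
  triplicate mini-cores reproduce the configured relative SD;
* triplicate mini piston cores (0-12 cm, and 12-24 cm near the shelf edge)
  at a subset of stations.

Ground truth is the noise-free latent field integrated by dense quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .model import (
    ANALYTES,
    DepthProfile,
    MiniCore,
    SedimentConstants,
    Slice,
    Station,
    StudyArea,
    ValidationError,
)
from .inventory import dry_mass_per_volume

#: (2,4'-, 4,4'-) isomer fractions of each parent analyte; 4,4' dominates
#: technical DDT and its weathering products.
ISOMER_SPLIT = {"ddt": (0.25, 0.75), "ddd": (0.20, 0.80), "dde": (0.15, 0.85)}


@dataclass
class BasinConfig:
    """Study conditions of the synthetic basin (units: m, cm, ug/kg)."""

    extent: tuple[float, float] = (40700.0, 20000.0)   # 814 km^2 rectangle
    n_stations: int = 54
    station_layout: str = "grid_jitter"                # | "uniform"
    seed: int = 0

    # DDT latent field: background + NE-SW band + hotspot (peak-depth amplitudes)
    ddt_background: float = 150.0
    band_amplitude_ddt: float = 3000.0
    band_width: float = 4000.0
    hotspot_center: tuple[float, float] = (5000.0, 5500.0)
    hotspot_radius: float = 1200.0
    hotspot_amplitude: float = 52000.0
    ddd_fraction: float = 0.4          # DDD latent = fraction x DDT latent

    # DDE latent field: band + shelf-edge gradient (north edge)
    dde_background: float = 100.0
    band_amplitude_dde: float = 1200.0
    shelf_amplitude: float = 2500.0
    shelf_decay: float = 5000.0

    # depth structure (cm)
    peak_depth_range: tuple[float, float] = (5.0, 9.0)
    peak_width: float = 1.8            # DDT/DDD Gaussian sigma
    dde_peak_width: float = 4.0
    surface_tail_dde: float = 0.5      # DDE surface-tail amplitude fraction
    dde_tail_scale: float = 5.0
    deep_background: float = 0.02      # residual shape floor (bioturbated)
    smear_scale: float = 0.0           # downward smearing (cm); 0 = off

    # cm-scale multiplicative noise (relative SD per analyte)
    cm_scale_cv: dict[str, float] = field(
        default_factory=lambda: {"ddt": 0.565, "ddd": 0.565, "dde": 0.2})
    slice_jitter_frac: float = 0.15    # per-slice jitter CV as fraction of cv

    # sampling
    slice_thickness: float = 2.0
    sampling_year: float = 2023.2
    n_minicore_stations: int = 14
    deep_minicore_band: float = 0.75   # stations with y > band*Ly also get 12-24

    # sediment physics
    ts_surface: float = 0.25           # % total solids at the interface
    ts_deep: float = 0.45              # ... at 30 cm (linear ramp)

    def __post_init__(self) -> None:
        if self.n_stations < 8:
            raise ValidationError("need >=8 stations")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValidationError("extent must be positive")
        for a, cv in self.cm_scale_cv.items():
            if cv < 0:
                raise ValidationError(f"negative cv for {a}")


@dataclass
class GroundTruth:
    """Noise-free mean inventory (mg/m^2) and burden (tonnes) per analyte,
    from dense quadrature of the latent field."""

    mean_inventory: dict[str, float]
    burden: dict[str, float]
    area_m2: float


# --------------------------------------------------------------------------
# Latent fields
# --------------------------------------------------------------------------

def _band_ridge(cfg: BasinConfig, x, y):
    """NE-SW Gaussian ridge through the basin center (0..1)."""
    cx, cy = cfg.extent[0] / 2, cfg.extent[1] / 2
    # distance from the line through (cx, cy) with direction (1, 1)/sqrt(2)
    d = np.abs((np.asarray(x) - cx) - (np.asarray(y) - cy)) / math.sqrt(2.0)
    return np.exp(-d ** 2 / (2.0 * cfg.band_width ** 2))


def latent_amplitude(cfg: BasinConfig, analyte: str, x, y):
    """Peak-depth concentration amplitude (ug/kg) of the latent field."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ridge = _band_ridge(cfg, x, y)
    if analyte in ("ddt", "ddd"):
        hx, hy = cfg.hotspot_center
        r2 = (x - hx) ** 2 + (y - hy) ** 2
        a = (cfg.ddt_background + cfg.band_amplitude_ddt * ridge
             + cfg.hotspot_amplitude * np.exp(-r2 / (2.0 * cfg.hotspot_radius ** 2)))
        return a * (cfg.ddd_fraction if analyte == "ddd" else 1.0)
    if analyte == "dde":
        d_shelf = cfg.extent[1] - y        # distance from the north edge
        return (cfg.dde_background + cfg.band_amplitude_dde * ridge
                + cfg.shelf_amplitude * np.exp(-d_shelf / cfg.shelf_decay))
    raise KeyError(analyte)


def depth_shape(cfg: BasinConfig, analyte: str, z, z_peak: float):
    """Dimensionless depth profile shape, ~1 at the peak horizon."""
    z = np.asarray(z, dtype=float)
    if analyte in ("ddt", "ddd"):
        s = (np.exp(-(z - z_peak) ** 2 / (2.0 * cfg.peak_width ** 2))
             + cfg.deep_background)
    elif analyte == "dde":
        s = (0.8 * np.exp(-(z - z_peak) ** 2 / (2.0 * cfg.dde_peak_width ** 2))
             + cfg.surface_tail_dde * np.exp(-z / cfg.dde_tail_scale)
             + cfg.deep_background)
    else:
        raise KeyError(analyte)
    if cfg.smear_scale > 0:
        # one-sided exponential kernel moving a little mass downward:
        # emulates bioturbation/blending that puts DDX into pre-peak strata
        dz = 0.25
        zz = np.arange(0.0, 60.0, dz)
        kern = np.exp(-zz / cfg.smear_scale)
        kern /= kern.sum()
        base = depth_shape(
            BasinConfig(**{**cfg.__dict__, "smear_scale": 0.0}), analyte, zz, z_peak)
        smeared = np.convolve(base, kern)[: len(zz)]
        s = np.interp(z, zz, smeared)
    return s


def _total_solids(cfg: BasinConfig, z):
    return cfg.ts_surface + (cfg.ts_deep - cfg.ts_surface) * np.asarray(z) / 30.0


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-preserving multiplicative lognormal noise at the given CV."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-0.5 * s2, math.sqrt(s2), size)


def _shared_patch(rng: np.random.Generator, cvs: dict[str, float],
                  scale: float = 1.0) -> dict[str, float]:
    """One mean-preserving lognormal patch factor per analyte driven by a
    single shared deviate: a contaminated patch is rich (or poor) in all
    congeners at once (the one-high-replicate pattern of real triplicates),
    while each analyte keeps its own CV."""
    z = rng.standard_normal()
    out = {}
    for a, cv in cvs.items():
        cv = cv * scale
        if cv == 0:
            out[a] = 1.0
        else:
            s2 = math.log(1.0 + cv * cv)
            out[a] = math.exp(-0.5 * s2 + math.sqrt(s2) * z)
    return out


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _station_coords(cfg: BasinConfig, rng: np.random.Generator) -> np.ndarray:
    lx, ly = cfg.extent
    n = cfg.n_stations
    if cfg.station_layout == "uniform":
        xy = np.column_stack([rng.uniform(0.02 * lx, 0.98 * lx, n),
                              rng.uniform(0.02 * ly, 0.98 * ly, n)])
    elif cfg.station_layout == "grid_jitter":
        nx = max(2, int(round(math.sqrt(n * lx / ly))))
        ny = max(2, int(math.ceil(n / nx)))
        gx = (np.arange(nx) + 0.5) * lx / nx
        gy = (np.arange(ny) + 0.5) * ly / ny
        pts = np.array([(x, y) for y in gy for x in gx])[:n]
        jitter = rng.uniform(-0.35, 0.35, (n, 2)) * [lx / nx, ly / ny]
        xy = np.clip(pts + jitter, [0.01 * lx, 0.01 * ly],
                     [0.99 * lx, 0.99 * ly])
    else:
        raise ValidationError(f"unknown station_layout {cfg.station_layout!r}")
    # snap the nearest station onto the hotspot (the survey targets it)
    hx, hy = cfg.hotspot_center
    i = int(np.argmin((xy[:, 0] - hx) ** 2 + (xy[:, 1] - hy) ** 2))
    xy[i] = (hx, hy)
    return xy


def _core_slices(cfg: BasinConfig, rng: np.random.Generator, x: float,
                 y: float, z_peak: float, amps: dict[str, float]) -> list[Slice]:
    n_sl = int(round(30.0 / cfg.slice_thickness))
    sub = np.linspace(0, 1, 7)[1:-1]  # sub-slice quadrature points
    patch = _shared_patch(rng, cfg.cm_scale_cv)
    slices = []
    for k in range(n_sl):
        zt = k * cfg.slice_thickness
        zb = zt + cfg.slice_thickness
        zq = zt + sub * cfg.slice_thickness
        jitter = _shared_patch(rng, cfg.cm_scale_cv,
                               scale=cfg.slice_jitter_frac)
        conc = {}
        for a, (f24, f44) in ISOMER_SPLIT.items():
            c = float(np.mean(depth_shape(cfg, a, zq, z_peak))) * amps[a] \
                * patch[a] * jitter[a]
            conc[f"{a}_24"] = f24 * c
            conc[f"{a}_44"] = f44 * c
        slices.append(Slice(z_top=zt, z_bottom=zb, conc=conc,
                            total_solids=float(_total_solids(cfg, 0.5 * (zt + zb)))))
    return slices


def _minicore(cfg: BasinConfig, rng: np.random.Generator, sid: str,
              replicate: int, interval: str, z_peak: float,
              amps: dict[str, float]) -> MiniCore:
    lo, hi = (0.0, 12.0) if interval == "0-12" else (12.0, 24.0)
    zq = np.linspace(lo, hi, 49)
    patch = _shared_patch(rng, cfg.cm_scale_cv)
    content = {}
    for a, (f24, f44) in ISOMER_SPLIT.items():
        c = float(np.trapezoid(depth_shape(cfg, a, zq, z_peak), zq)
                  / (hi - lo)) * amps[a] * patch[a]
        content[f"{a}_24"] = f24 * c
        content[f"{a}_44"] = f44 * c
    return MiniCore(station_id=sid, replicate=replicate, interval=interval,
                    content=content)


def generate_basin(cfg: BasinConfig | None = None,
                   ) -> tuple[list[Station], GroundTruth, StudyArea]:
    """Generate stations with sliced profiles and triplicate mini-cores,
    the noise-free ground truth, and the study polygon. Deterministic under
    ``cfg.seed``."""
    cfg = cfg or BasinConfig()
    rng = np.random.default_rng(cfg.seed)
    lx, ly = cfg.extent
    area = StudyArea(polygon=box(0.0, 0.0, lx, ly))
    xy = _station_coords(cfg, rng)

    # mini-core stations: a regular subset across the basin ("A-series")
    step = max(1, cfg.n_stations // max(cfg.n_minicore_stations, 1))
    mc_idx = set(range(0, cfg.n_stations, step)[: cfg.n_minicore_stations]) \
        if cfg.n_minicore_stations else set()

    stations: list[Station] = []
    for i, (x, y) in enumerate(xy):
        sid = f"S{i + 1:02d}"
        z_peak = rng.uniform(*cfg.peak_depth_range)
        amps = {a: float(latent_amplitude(cfg, a, x, y)) for a in ISOMER_SPLIT}
        profile = DepthProfile(_core_slices(cfg, rng, x, y, z_peak, amps))
        minicores = []
        if i in mc_idx:
            intervals = ["0-12"]
            if y > cfg.deep_minicore_band * ly:
                intervals.append("12-24")
            for rep in (1, 2, 3):
                for iv in intervals:
                    minicores.append(_minicore(cfg, rng, sid, rep, iv,
                                               z_peak, amps))
        stations.append(Station(
            id=sid, x=float(x), y=float(y),
            water_depth=float(900.0 - 40.0 * y / ly),
            sampling_year=cfg.sampling_year, profile=profile,
            minicores=minicores))
    truth = ground_truth_burden(cfg)
    return stations, truth, area


def ground_truth_burden(cfg: BasinConfig | None = None,
                        resolution: float = 50.0,
                        constants: SedimentConstants | None = None) -> GroundTruth:
    """Dense-grid quadrature (<= ``resolution``-m cells) of the noise-free
    inventory field over the basin polygon.

    The depth integral uses the central peak depth; the station-to-station
    peak-depth jitter leaves the depth integral essentially unchanged (the
    Gaussian mass is conserved far from the 30-cm boundary).
    """
    cfg = cfg or BasinConfig()
    constants = constants or SedimentConstants()
    lx, ly = cfg.extent
    z = np.arange(0.0, 30.0, 0.05) + 0.025
    rho = dry_mass_per_volume(_total_solids(cfg, z), constants)
    z_peak = 0.5 * sum(cfg.peak_depth_range)
    # ug/kg -> mg/m^2 per unit amplitude: sum shape*rho*dz*0.01
    depth_factor = {a: float(np.sum(depth_shape(cfg, a, z, z_peak) * rho)
                             * 0.05 * 0.01)
                    for a in ISOMER_SPLIT}
    nx = max(1, int(math.ceil(lx / resolution)))
    ny = max(1, int(math.ceil(ly / resolution)))
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * lx / nx,
                         (np.arange(ny) + 0.5) * ly / ny)
    mean_inv = {a: float(np.mean(latent_amplitude(cfg, a, gx, gy))
                         * depth_factor[a])
                for a in ISOMER_SPLIT}
    mean_inv["ddx"] = sum(mean_inv[a] for a in ISOMER_SPLIT)
    area_m2 = lx * ly
    burden = {a: m * area_m2 * 1e-9 for a, m in mean_inv.items()}
    return GroundTruth(mean_inventory=mean_inv, burden=burden, area_m2=area_m2)
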