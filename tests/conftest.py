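import numpy as np
import pytest
from shapely.geometry import box

import ddxburden as d

#: rectangle with the basin's 814 km^2 area
RECT_EXTENT = (40700.0, 20000.0)


@pytest.fixture(scope="session")
def rect_area() -> d.StudyArea:
    return d.StudyArea(polygon=box(0.0, 0.0, *RECT_EXTENT))


@pytest.fixture(scope="session")
def small_basin():
    """A small synthetic basin shared by read-only tests."""
    return d.generate_basin(d.BasinConfig(seed=7, n_stations=20,
                                          n_minicore_stations=6))


def uniform_station(sid: str, x: float, y: float,
                    analyte_inventories: dict[str, float],
                    sampling_year: float = 2023.0) -> d.Station:
    """A station whose depth-uniform profile yields exactly the requested
    per-analyte inventories (mg/m^2 over 30 cm), using total_solids = 1 so
    the dry bulk density equals the grain density."""
    rho = d.SedimentConstants().grain_density
    conc = {}
    for a, target in analyte_inventories.items():
        c_total = target / (rho * 30.0 * 0.01)
        for iso in d.ANALYTES[a]:
            conc[iso] = c_total / 2.0
    slices = [d.Slice(z_top=2.0 * k, z_bottom=2.0 * (k + 1),
                      conc=dict(conc), total_solids=1.0) for k in range(15)]
    return d.Station(id=sid, x=x, y=y, water_depth=800.0,
                     sampling_year=sampling_year,
                     profile=d.DepthProfile(slices))


def uniform_stations_grid(analyte_inventories: dict[str, float],
                          nx: int = 6, ny: int = 4,
                          extent=RECT_EXTENT) -> list[d.Station]:
    """Stations on a regular grid spanning the rectangle, all with the same
    uniform profile."""
    xs = np.linspace(0.02 * extent[0], 0.98 * extent[0], nx)
    ys = np.linspace(0.02 * extent[1], 0.98 * extent[1], ny)
    out = []
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            out.append(uniform_station(f"G{i}{j}", float(x), float(y),
                                       analyte_inventories))
    return out
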