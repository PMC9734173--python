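import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from reefdrift import ocean

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_domain():
    """The full 29-region / 141-reef shelf domain."""
    return ocean.generate_domain(seed=1)


@pytest.fixture(scope="session")
def small_domain():
    """A 12-region domain (3 sectors × 2 rows × 2 bands) for fast runs."""
    cfg = ocean.DomainConfig(
        rows_per_sector=2, n_regions=12, n_reefs_total=24,
    )
    return ocean.generate_domain(cfg, seed=2)


def make_uniform_field(
    u=0.0, v=0.0, n_hours=601, ny=24, nx=8, spacing=10.0, n_layers=1, layer_values=None
):
    """Spatially uniform, time-constant field; per-layer (u, v) overrides
    via ``layer_values`` = [(u0, v0), ...]."""
    uu = np.full((n_hours, n_layers, ny, nx), u, dtype=np.float32)
    vv = np.full((n_hours, n_layers, ny, nx), v, dtype=np.float32)
    if layer_values is not None:
        for li, (ul, vl) in enumerate(layer_values):
            uu[:, li] = ul
            vv[:, li] = vl
    depths = np.array([1.0, 3.0, 6.0][:n_layers]) if n_layers <= 3 else np.arange(n_layers) + 1.0
    return ocean.VelocityField(
        u=uu, v=vv,
        time_hours=np.arange(n_hours, dtype=float),
        depths=depths,
        grid_x=(np.arange(nx) + 0.5) * spacing,
        grid_y=(np.arange(ny) + 0.5) * spacing,
    )


def make_rotation_field(omega_per_s, radius_extent=60.0, spacing=5.0, n_hours=2000):
    """Solid-body rotation u=-ω·(y-yc), v=ω·(x-xc) around the grid center.

    Bilinear interpolation is exact for this linear field, so the gridded
    representation introduces no spatial error.
    """
    n = int(2 * radius_extent / spacing)
    coords = (np.arange(n) + 0.5) * spacing
    xc = yc = coords.mean()
    xx, yy = np.meshgrid(coords, coords)
    # positions in km, velocities in m/s: 1000 factor makes dx/dt = -omega*(y-yc)
    u = (-omega_per_s * 1000.0 * (yy - yc)).astype(np.float32)
    v = (omega_per_s * 1000.0 * (xx - xc)).astype(np.float32)
    uu = np.broadcast_to(u, (n_hours, 1, n, n)).copy()
    vv = np.broadcast_to(v, (n_hours, 1, n, n)).copy()
    fld = ocean.VelocityField(
        u=uu, v=vv,
        time_hours=np.arange(n_hours, dtype=float),
        depths=np.array([1.0]),
        grid_x=coords, grid_y=coords,
    )
    return fld, (xc, yc)
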