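import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_table():
    """One default-config synthetic site table with its RD indices."""
    from resdiv import radar, synthetic

    table = synthetic.generate_site_table(synthetic.GeneratorConfig())
    indices = radar.compute_indices(
        table[list(synthetic.RESOURCE_COLUMNS)], shift="auto"
    )
    return table, indices


def discretized_geometry(radii, steps=100_000):
    """Numerical radar-chart oracle: polygonal arcs plus explicit radial walk.

    Places the sorted radii in ascending order, approximates each arc by
    chords at ~``steps`` angular subdivisions in total, sums triangle-fan
    areas, and measures the radial boundary segments directly from the
    cyclic arrangement (adjacent differences plus the closing segment).
    Independent of the closed forms in resdiv.radar.
    """
    r = np.sort(np.asarray(radii, dtype=float))
    n = r.size
    per_sector = max(steps // n, 8)
    dtheta = (2 * np.pi / n) / per_sector
    arc_len = float(np.sum(r * per_sector * 2.0 * np.sin(dtheta / 2.0)))
    area = float(np.sum(0.5 * r**2 * np.sin(dtheta) * per_sector))
    cyc = np.concatenate([r, r[:1]])
    radial = float(np.sum(np.abs(np.diff(cyc))))
    return area, arc_len + radial
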