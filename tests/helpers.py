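"""Shared scene builders for the test suite."""

from __future__ import annotations

import numpy as np

from gcmorph.core import MissingWedge
from gcmorph.synth import (
    DEFAULT_NOISE_SD,
    ParticleSpec,
    ScenePlan,
    make_bundle,
    make_filament,
    make_mt,
    render_scene,
)

WEDGE = MissingWedge()


def render_one_filament(repeat_class="long", seed=0, length=300.0, noise=DEFAULT_NOISE_SD,
                        wedge=WEDGE, phase_offset=0):
    f = make_filament((20, 20, 20), (1, 0, 0), length, repeat_class,
                      phase_offset=phase_offset)
    plan = ScenePlan(shape=(int(length) + 40, 40, 40), voxel_size=1.0,
                     filaments=[f], wedge=wedge, noise_sd=noise, seed=seed)
    vol, truth = render_scene(plan)
    return vol, f


def render_one_mt(seed=0, length=200.0, noise=DEFAULT_NOISE_SD, wedge=WEDGE, **kw):
    m = make_mt((20, 32, 32), (1, 0, 0), length, **kw)
    plan = ScenePlan(shape=(int(length) + 40, 64, 64), voxel_size=1.0,
                     mts=[m], wedge=wedge, noise_sd=noise, seed=seed)
    vol, truth = render_scene(plan)
    return vol, m


def render_pair_bundle(seed=0, length=400.0, period=37.1, noise=DEFAULT_NOISE_SD):
    b = make_bundle((20, 35, 35), (1, 0, 0), length, n_wide=2, n_high=1,
                    crosslink_period=period)
    plan = ScenePlan(shape=(int(length) + 40, 70, 70), voxel_size=1.0,
                     bundles=[b], wedge=WEDGE, noise_sd=noise, seed=seed)
    vol, truth = render_scene(plan)
    return vol, b


def hex_points(n_wide, n_high, a, jitter=0.0, rng=None):
    """Ideal (optionally jittered) hexagonal lattice points in 2D."""
    pts = []
    for r in range(n_high):
        for c in range(n_wide):
            pts.append((c * a + (r % 2) * a / 2, r * a * np.sqrt(3) / 2))
    pts = np.asarray(pts, dtype=float)
    if jitter > 0:
        pts = pts + rng.normal(0, jitter, pts.shape)
    return pts


def sparse_particle_mt(rng, length=1200.0, spacing=40.0):
    """An MT carrying sparse particles with radii ~ N(3.9, 0.85), truncated."""
    parts, true_d = [], []
    for s in np.arange(25.0, length - 25.0, spacing):
        r = float(np.clip(rng.normal(3.9, 0.85), 1.95, 7.35))
        off = float(rng.uniform(0, max(0.0, min(1.5, 7.5 - r))))
        parts.append(ParticleSpec(axial_position=float(s), radial_offset=off,
                                  diameter=2 * r, azimuth=float(rng.uniform(0, 360))))
        true_d.append(2 * r)
    return make_mt((20, 32, 32), (1, 0, 0), length, particles=parts), true_d
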