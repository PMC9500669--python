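"""Shared fixtures and helpers for the sarcolattice test suite.

All fixtures are generated programmatically; there are no stored image files.
Scenes are kept at desk scale (160-256 px frames) so the whole suite runs in
minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import fields as dc_fields

import pytest

from sarcolattice import FiberScene, generate_striated_fiber
from sarcolattice.synth import auto_vernier_events

#: Band amplitude 1.0 with Gaussian read noise 0.2 -> SNR 5, the noisiest
#: condition the structural read-outs are specified to tolerate.
SNR5_NOISE_SD = 0.2


def scene_with(scene: FiberScene, **overrides) -> FiberScene:
    """Copy a frozen FiberScene with some fields replaced."""
    kw = {f.name: getattr(scene, f.name) for f in dc_fields(scene)}
    kw.update(overrides)
    return FiberScene(**kw)


def small_fiber_scene(**overrides) -> FiberScene:
    """A 400 um^2 fiber (25 x 16 um) in a 160 px frame at 0.2 um/px."""
    base = dict(
        shape=(1, 160, 160),
        fiber_axis_angle_deg=15.0,
        fiber_length_um=25.0,
        fiber_width_um=16.0,
    )
    base.update(overrides)
    return FiberScene(**base)


def vernier_scene(n_events: int, placement_seed: int, **overrides) -> FiberScene:
    """Small fiber with n auto-placed Y-junction verniers (>= 2 spacings apart)."""
    scene = small_fiber_scene(**overrides)
    events = auto_vernier_events(scene, n_events, seed=placement_seed)
    return scene_with(scene, vernier_events=events)


def match_events(
    detected: list[tuple[float, float]],
    truth: list[tuple[float, float]],
    radius_um: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    used: set[int] = set()
    tp = 0
    for tx, ty in truth:
        best, best_d = None, radius_um
        for i, (x, y) in enumerate(detected):
            if i in used:
                continue
            d = math.hypot(x - tx, y - ty)
            if d <= best_d:
                best_d, best = d, i
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(detected) - tp, len(truth) - tp


@pytest.fixture
def parallel_fiber():
    """Noise-free, defect-free, perfectly parallel lattice with its truth."""
    return generate_striated_fiber(small_fiber_scene(), seed=0)
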