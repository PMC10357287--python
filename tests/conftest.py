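"""Shared fixtures: constructed vessel geometries and cached simulated
cohorts (session scope, so the expensive generations run once)."""

import math

import numpy as np
import pytest
from hypothesis import settings

from iliorisk.centerline_geometry import Centerline
from iliorisk.simulate import SimulationConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def polyline_vessel(segments, diameter=7.0, step=1.0):
    """Build a centerline from (length_mm, direction) straight segments
    joined at sharp vertices, sampled every ``step`` mm."""
    pts = [np.zeros(3)]
    for length, direction in segments:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        n = max(1, int(round(length / step)))
        start = pts[-1]
        pts.extend(start + (i * length / n) * d for i in range(1, n + 1))
    pts = np.asarray(pts)
    return Centerline.from_arrays(pts, np.full(len(pts), float(diameter)))


def elbow_vessel(angles_deg, gap=50.0, lead=40.0, diameter=7.0):
    """Planar vessel with sharp elbows of the given turn angles separated
    by straight runs — the constructed-geometry oracle for curve
    detection (all turns in the xz-plane, alternating sense would keep it
    planar; here all bend the same way)."""
    heading = 0.0
    segments = [(lead, (0.0, 0.0, 1.0))]
    for ang in angles_deg:
        heading += math.radians(ang)
        segments.append((gap, (math.sin(heading), 0.0, math.cos(heading))))
    return polyline_vessel(segments, diameter=diameter)


def single_elbow(angle_deg=45.0, arm=40.0, diameter=6.0, step=1.0):
    """One sharp planar elbow with the vertex exactly on a sample point."""
    th = math.radians(angle_deg)
    return polyline_vessel([(arm, (0.0, 0.0, 1.0)),
                            (arm, (math.sin(th), 0.0, math.cos(th)))],
                           diameter=diameter, step=step)


@pytest.fixture
def straight_vessel():
    pts = np.column_stack([np.zeros(206), np.zeros(206),
                           np.arange(206.0)])
    return Centerline.from_arrays(pts, np.full(206, 7.0))


@pytest.fixture
def three_elbow_vessel():
    return elbow_vessel([30.0, 40.0, 50.0])


@pytest.fixture(scope="session")
def cohort_10k():
    """Default study conditions at n = 10,000 (incidence calibration)."""
    return simulate_cohort(SimulationConfig(n_patients=10_000, seed=1))


@pytest.fixture(scope="session")
def cohort_20k():
    """Default study conditions at n = 20,000 (parameter recovery)."""
    return simulate_cohort(SimulationConfig(n_patients=20_000, seed=2))


@pytest.fixture(scope="session")
def cohort_small():
    """A quick 600-patient cohort for pipeline-level tests."""
    return simulate_cohort(SimulationConfig(n_patients=600, seed=5))
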