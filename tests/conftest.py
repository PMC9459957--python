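"""Shared fixtures: the published cube-measurement table and cached scans."""

import numpy as np
import pytest

import phenoscan as ps
from phenoscan.organs import LabeledScan

# The twelve cube-edge measurements (edge id, reference cm, measured cm)
# reported for the physical platform's 5.5 cm reference cube.
TABLE2_EDGES = [
    ("U1", 5.5, 5.4383),
    ("U2", 5.5, 5.5573),
    ("D1", 5.5, 5.3808),
    ("D2", 5.5, 5.3692),
    ("U3", 5.5, 5.5431),
    ("U4", 5.5, 5.6141),
    ("D3", 5.5, 5.3308),
    ("D4", 5.5, 5.3552),
    ("L1", 5.5, 5.4363),
    ("L2", 5.5, 5.4902),
    ("L3", 5.5, 5.3051),
    ("L4", 5.5, 5.6002),
]


@pytest.fixture(scope="session")
def table2_measurements():
    return [ps.EdgeMeasurement(e, r, m) for e, r, m in TABLE2_EDGES]


@pytest.fixture(scope="session")
def cube_calib():
    # sensor 1 m from the disc axis, 20 cm above the disc, untilted
    return ps.PlatformCalibration(d=100.0, h=20.0)


@pytest.fixture(scope="session")
def cube_scene():
    return ps.build_cube(5.5)


@pytest.fixture(scope="session")
def cube_scan_noiseless(cube_scene, cube_calib):
    scanner = ps.ScannerConfig(rng_seed=1)
    turntable = ps.TurntableConfig(step_deg=3.0)
    profiles, gt = ps.simulate_scan(cube_scene, scanner, turntable, cube_calib,
                                    noiseless=True)
    return profiles, gt, ps.reconstruct_scan(profiles, cube_calib)


@pytest.fixture(scope="session")
def cube_scan_noisy(cube_scene, cube_calib):
    scanner = ps.ScannerConfig(rng_seed=2)
    turntable = ps.TurntableConfig(step_deg=3.0)
    profiles, gt = ps.simulate_scan(cube_scene, scanner, turntable, cube_calib)
    return profiles, gt, ps.reconstruct_scan(profiles, cube_calib)


def make_seedling_benchmark(n_plants: int, seed: int, step_deg: float = 3.0):
    """Scan a population of random seedlings and return labeled scans.

    Ground-truth organ labels come from the simulator's ray-surface hits and
    are index-aligned with the noisy returns.
    """
    rng = np.random.default_rng(seed)
    calib = ps.PlatformCalibration(d=100.0, h=25.0)
    turntable = ps.TurntableConfig(step_deg=step_deg)
    scans = []
    for i in range(n_plants):
        params = ps.random_seedling_params(rng)
        scene = ps.build_seedling(params)
        scanner = ps.ScannerConfig(rng_seed=int(rng.integers(0, 2**31 - 1)))
        profiles, gt = ps.simulate_scan(scene, scanner, turntable, calib)
        cloud = ps.reconstruct_scan(profiles, calib)
        scans.append(
            (params, scene, LabeledScan(f"plant{i:02d}", cloud, gt.labels,
                                        n_leaves=params.n_leaves))
        )
    return scans


@pytest.fixture(scope="session")
def seedling_benchmark_small():
    """Six scanned seedlings: enough for a quick end-to-end split/train run."""
    return make_seedling_benchmark(6, seed=42)
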