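"""Shared fixtures: seeded synthetic studies reused across the suite.

Studies are session-scoped because generating and analyzing 200-molecule
populations takes a few seconds each; every consumer treats the frames as
read-only.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from tethermorph.pipeline import AnalysisParams, analyze_population
from tethermorph.synthetic import ScanSpec, generate_population, get_preset

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: One canonical seed for the study fixtures.
STUDY_SEED = 0
STUDY_N = 200


def clean_scan_spec() -> ScanSpec:
    """Idealized render: no tip, no noise, no slant."""
    return ScanSpec(tip_radius_nm=0.0, noise_sd_nm=0.0, slant_row_sd_nm=0.0,
                    slant_plane_gradient_nm_per_px=0.0)


def run_study(preset: str, scan: ScanSpec, n: int = STUDY_N,
              seed: int = STUDY_SEED, feature: str = "bubble"):
    pop = dataclasses.replace(get_preset(preset), n_molecules=n, seed=seed)
    fields = generate_population(pop, scan, return_masks=True)
    return analyze_population(fields, AnalysisParams(feature=feature),
                              with_truth=True)


@pytest.fixture(scope="session")
def clean_scan() -> ScanSpec:
    return clean_scan_spec()


@pytest.fixture(scope="session")
def wt_clean(clean_scan):
    """Wild-type preset, ideal render: metrics + rejections frames."""
    return run_study("wt", clean_scan)


@pytest.fixture(scope="session")
def wt_noisy():
    """Wild-type preset under the default scan (3 nm tip, noise, slant)."""
    return run_study("wt", ScanSpec())


@pytest.fixture(scope="session")
def dhinge_clean(clean_scan):
    return run_study("dhinge", clean_scan)


@pytest.fixture(scope="session")
def dhinge_noisy():
    return run_study("dhinge", ScanSpec())


@pytest.fixture(scope="session")
def labeled_clean(clean_scan):
    """Antibody-labelled wild type, ideal render, 150 molecules."""
    return run_study("wt-ha", clean_scan, n=150, feature="antibody")
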