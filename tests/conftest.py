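"""Shared fixtures: synthetic embryos rendered once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from embryofish import (
    ActivationConfig,
    RenderConfig,
    call_spots,
    log_filter,
    make_dorsal_profile,
    render_embryo,
    select_threshold,
    simulate_activation,
    subtract_local_background,
)


@pytest.fixture(scope="session")
def profile():
    return make_dorsal_profile(sigma=4.0, half_width=9)


@pytest.fixture(scope="session")
def clean_embryo(profile):
    """Noise-free embryo with well-separated spots (single alleles)."""
    cfg = ActivationConfig(
        p_mid=1 / 15, T=15.0, n_nuclei_per_column=8, alleles_per_nucleus=1, seed=0
    )
    table = simulate_activation(profile, cfg)
    rcfg = RenderConfig(
        seed=0,
        shot_noise_scale=0.0,
        read_noise_sigma=0.0,
        baseline=0.0,
        mrna_per_column=5,
        min_separation=9.0,
        enforce_separation=True,
    )
    stacks, truth = render_embryo(table, profile, rcfg)
    return stacks, truth


@pytest.fixture(scope="session")
def noisy_embryo(profile):
    """Default-noise embryo at the standard study conditions (ratio 70)."""
    cfg = ActivationConfig(p_mid=1 / 15, T=15.0, n_nuclei_per_column=8, seed=1)
    table = simulate_activation(profile, cfg)
    stacks, truth = render_embryo(table, profile, RenderConfig(seed=101))
    return stacks, truth


def detect_3d(stacks):
    """Standard 3D single-molecule detection chain used across tests."""
    stack = stacks["fish"]
    bgsub = subtract_local_background(stack, radius=5)
    resp = log_filter(bgsub, size=9, sigma=(1.0, 1.5, 1.5))
    scan = select_threshold(resp)
    spots = call_spots(
        resp,
        scan.chosen,
        connectivity=18,
        measurement=stack,
        measure_dilate=3.0,
        subtract_region_background=True,
    )
    return spots, scan


@pytest.fixture(scope="session")
def noisy_detection(noisy_embryo):
    stacks, truth = noisy_embryo
    spots, scan = detect_3d(stacks)
    return spots, scan, truth
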