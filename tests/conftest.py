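"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from qustex.glcm_texture import GLCMConfig
from qustex.phantom_sim import (
    PulseModel,
    generate_reference,
    generate_scatterer_field,
    synthesize_rf,
)


@pytest.fixture(scope="session")
def pulse() -> PulseModel:
    return PulseModel(
        center_frequency=7e6,
        fractional_bandwidth=5.0 / 7.0,
        sampling_frequency=40e6,
    )


@pytest.fixture(scope="session")
def reference(pulse):
    return generate_reference(
        pulse, n_lines=96, line_spacing=3e-4, seed=7, extent_axial=0.014
    )


@pytest.fixture(scope="session")
def homogeneous_rf(pulse):
    """Fully developed speckle from a single homogeneous field (30 um)."""
    field = generate_scatterer_field(
        (0.012, 64 * 3e-4), 150.0, 30.0, amplitude_cv=0.2, seed=11
    )
    return synthesize_rf(field, pulse, n_lines=64, line_spacing=3e-4)


def brute_force_glcm(
    grid: np.ndarray, missing: np.ndarray, config: GLCMConfig
) -> np.ndarray:
    """Independent double-loop pair counter (the oracle for compute_glcm).

    Walks every pixel and every (distance, angle) offset explicitly and
    accumulates counts, skipping pairs that touch a missing pixel.
    Returns the normalized matrix, or None if there are no valid pairs.
    """
    L = config.levels
    counts = np.zeros((L, L))
    h, w = grid.shape
    for d in config.distances:
        for ang in config.angles:
            rad = np.deg2rad(ang)
            dr = -int(round(d * np.sin(rad)))
            dc = int(round(d * np.cos(rad)))
            for r in range(h):
                for c in range(w):
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < h and 0 <= c2 < w):
                        continue
                    if missing[r, c] or missing[r2, c2]:
                        continue
                    counts[grid[r, c], grid[r2, c2]] += 1
    if config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return None
    return counts / total
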