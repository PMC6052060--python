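"""Shared fixtures: all synthetic, generated at session start."""

import numpy as np
import pytest
import trimesh

import curvedcell as cc


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit-radius icosphere with 2562 vertices."""
    return trimesh.creation.icosphere(subdivisions=4)


@pytest.fixture(scope="session")
def spherocylinder():
    """Exact discretised spherocylinder: r = 0.5 μm, body L = 3 μm."""
    return cc.generate_cell(cc.CellSpec(radius_um=0.5, length_um=3.0, seed=1))


@pytest.fixture(scope="session")
def modulated_cell():
    """Sinusoidally modulated rod: a = 0.1, λ = 1 μm (IDD = 0.1/√2)."""
    return cc.generate_cell(
        cc.CellSpec(mod_amplitude=0.1, mod_wavelength=1.0, seed=2)
    )


@pytest.fixture(scope="session")
def step_paint():
    """Step enrichment: 1.2 below 2 μm⁻², 0.5 above, noise-free."""
    return cc.PaintSpec(kind="step", low=1.2, high=0.5, cutoff=2.0)


@pytest.fixture(scope="session")
def step_population(step_paint):
    """20 step-painted cells with 20% multiplicative noise."""
    from dataclasses import replace

    strain = cc.preset("wt")
    strain = replace(
        strain, paint=replace(step_paint, noise_cv=0.2, cyto_fraction=0.05)
    )
    cells, psets, truth = cc.generate_population(strain, 20, master_seed=11)
    return cells, psets, truth


@pytest.fixture(scope="session")
def coarse_cell():
    """Small cell (few hundred faces) for brute-force oracle comparisons."""
    return cc.generate_cell(
        cc.CellSpec(length_um=1.5, resolution_um=0.2, seed=5)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180718)
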