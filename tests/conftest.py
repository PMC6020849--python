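"""Shared fixtures.

The RCWA solves and the 10-frame noisy adhesion sequence are expensive, so
they are computed once per session and shared across test modules.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import promscope as p


@pytest.fixture(scope="session")
def stack():
    return p.GratingStack()


@pytest.fixture(scope="session")
def water():
    return p.Medium()


@pytest.fixture(scope="session")
def design_spectrum(stack, water):
    """Reflectance around the resonance on a 0.1 nm grid."""
    return p.simulate_spectrum(stack, water, np.arange(620.0, 636.0001, 0.1))


@pytest.fixture(scope="session")
def design_fit(design_spectrum):
    return p.locate_resonance(design_spectrum)


@pytest.fixture(scope="session")
def design_profile(stack, water, design_fit):
    return p.field_profile(stack, water, design_fit.pwv_nm)


@pytest.fixture(scope="session")
def resonator(design_fit, design_profile, stack, water):
    return p.resonator_from_simulation(design_fit, design_profile,
                                       stack.period_nm, water)


@pytest.fixture(scope="session")
def instrument_grid():
    return np.round(np.arange(615.0, 640.0001, 0.2), 10)


@pytest.fixture(scope="session")
def adhesion_sequence():
    """Canonical 10-frame noisy adhesion series, fully fitted.

    scene -> render (noise SD 0.01, fixed seed) -> per-pixel fits ->
    shift images against the pre-attachment background frame.
    """
    scene = p.generate_scene(p.SceneParams(n_frames=10), seed=7)
    inst = p.InstrumentModel(noise_sd=0.01, seed=7)
    cubes = p.render_sequence(scene, inst, seed=7)
    reference = p.render_reference_cube(scene.masks[0].shape,
                                        p.InstrumentModel(noise_sd=0.0))
    bg_truth = (np.full(scene.masks[0].shape, 626.0),
                np.full(scene.masks[0].shape, 0.90))
    bg_cube = p.render_cube(bg_truth, p.InstrumentModel(noise_sd=0.01, seed=7),
                            frame_index=0, seed=1007)
    maps = [p.fit_cube(c, reference) for c in cubes]
    bg_maps = p.fit_cube(bg_cube, reference)
    shifts = [p.shift_images(m, bg_maps) for m in maps]
    return {"scene": scene, "instrument": inst, "cubes": cubes,
            "maps": maps, "bg_maps": bg_maps, "shifts": shifts}
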