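import numpy as np
import pytest

import flimpheno as fp


@pytest.fixture(scope="session")
def irf():
    return fp.gaussian_irf()


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 two-phenotype scene with rendered cubes (session-cached)."""
    profs = fp.default_profiles()
    spec = fp.SceneSpec(shape=(96, 96), n_cells=6, cell_radius=(9.0, 12.0),
                        nucleus_radius=(3.0, 5.0), seed=11)
    scene = fp.generate_scene(
        spec, [profs["glycolysis_inhibited"], profs["oxphos_inhibited"]])
    irf = fp.gaussian_irf()
    cubes = fp.render_tcspc(scene, irf, rng_seed=12)
    return scene, cubes, irf


@pytest.fixture(scope="session")
def fitted_scene(small_scene):
    scene, (nadh_cube, fad_cube), irf = small_scene
    nadh = fp.fit_image(nadh_cube, irf)
    fad = fp.fit_image(fad_cube, irf)
    return scene, nadh, fad


@pytest.fixture(scope="session")
def feature_table():
    """2x300 cells drawn from the two inhibition presets."""
    return fp.sample_cell_features(
        {"glycolysis_inhibited": 300, "oxphos_inhibited": 300}, seed=21)
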