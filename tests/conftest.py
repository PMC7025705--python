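import numpy as np
import pytest

import florasym as fs
from florasym import align, symmetry


def tiny_params(**overrides) -> fs.GeneratorParams:
    """Small noise-free-by-default population for fast unit tests."""
    base = dict(
        n_trees_per_sex=2, flowers_per_tree=3, n_imaging=1, n_digitisation=1,
        sigma_sym=0.0, sigma_lat=0.0, sigma_trans=0.0, sigma_petal=0.0,
        sigma_imaging=0.0, sigma_digit=0.0, female_size_factor=1.0,
        female_asym_factor=1.0, tree_effect_sd=0.0, seed=0,
    )
    base.update(overrides)
    return fs.GeneratorParams(**base)


@pytest.fixture(scope="session")
def mixed_population():
    """A small population with variation in every subspace plus noise."""
    params = tiny_params(
        flowers_per_tree=4, n_imaging=2, n_digitisation=2,
        sigma_sym=0.08, sigma_lat=0.04, sigma_trans=0.025, sigma_petal=0.004,
        sigma_imaging=0.5, sigma_digit=0.5, female_size_factor=0.845,
        female_asym_factor=1.3, tree_effect_sd=0.05, seed=42,
    )
    data, truth = fs.generate_population(params)
    return params, data, truth


@pytest.fixture(scope="session")
def mixed_aligned(mixed_population):
    """Expanded + GPA-with-sliding alignment of the mixed population."""
    _, data, _ = mixed_population
    expanded = symmetry.expand_symmetry_group(data)
    alignment = align.gpa(expanded, sliders=align.default_slider_spec())
    return data, expanded, alignment
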