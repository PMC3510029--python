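import warnings

import pytest

import chromredist as cr


def small_spec(**overrides) -> cr.SyntheticSpec:
    base = dict(n_chromosomes=2, chromosome_length=60_000, n_genes=24,
                n_transposons=10, seed=11)
    base.update(overrides)
    return cr.SyntheticSpec(**base)


@pytest.fixture(scope="session")
def small_bundle() -> cr.SyntheticBundle:
    return cr.generate_bundle(small_spec())


@pytest.fixture(scope="session")
def noiseless_bundle() -> cr.SyntheticBundle:
    return cr.generate_bundle(small_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def default_bundle() -> cr.SyntheticBundle:
    """The full-scale study conditions: 3 x 200 kb, noise 0.3, delta 1.5."""
    return cr.generate_bundle(cr.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def default_norm(default_bundle):
    return {key: cr.log2_ratio_normalize(track, default_bundle.control)
            for key, track in default_bundle.tracks.items()}


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
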