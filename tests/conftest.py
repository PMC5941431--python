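import pytest

from svseg import (PhantomSpec, SlicConfig, build_knn_graph, estimate_noise,
                   extract_features, generate_phantom, run_slic,
                   two_slab_phantom)

# The standard study phantom: 64^3 three-tissue volume at 5% Rician noise and
# 20% INU, segmented with q=500 supervoxels.  Built once per session; the
# supervoxel and graph stages are deterministic so every test sees the same
# object.


@pytest.fixture(scope="session")
def study_phantom():
    return generate_phantom(PhantomSpec(shape=(64, 64, 64), noise_percent=0.05,
                                        inu_percent=0.2, rng_seed=7))


@pytest.fixture(scope="session")
def study_noise(study_phantom):
    return estimate_noise(study_phantom.intensity)


@pytest.fixture(scope="session")
def study_svmap(study_phantom, study_noise):
    return run_slic(study_phantom.intensity, SlicConfig(q=500), study_noise)


@pytest.fixture(scope="session")
def study_graph(study_phantom, study_svmap, study_noise):
    features = extract_features(study_phantom.intensity, study_svmap, study_noise)
    return build_knn_graph(features, K=10)


@pytest.fixture(scope="session")
def slab():
    """Noiseless two-slab phantom, intensities 0 / 200, full mask."""
    return two_slab_phantom((32, 32, 32))
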