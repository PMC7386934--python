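import pytest

import cordmap as cm


@pytest.fixture(scope="session")
def atlas():
    return cm.build_atlas()


@pytest.fixture(scope="session")
def protocol():
    return cm.generate_protocol(seed=3)


@pytest.fixture(scope="session")
def physio(protocol):
    return cm.simulate_physio(protocol.duration_s, seed=4)


@pytest.fixture(scope="session")
def truth(atlas):
    return cm.make_lateralized_truth(atlas, lr_index=0.3, dv_index=0.0,
                                     n_voxels=320, amplitude=0.71)


@pytest.fixture(scope="session")
def noisy_run(atlas, protocol, truth, physio):
    return cm.simulate_run(atlas, protocol, truth, physio,
                           cm.NoiseSpec(spike_volumes=(100,)), seed=5)


@pytest.fixture(scope="session")
def clean_run(atlas, protocol, truth, physio):
    return cm.simulate_run(atlas, protocol, truth, physio,
                           cm.NoiseSpec.off(), seed=5)


@pytest.fixture(scope="session")
def analyzed(noisy_run, atlas):
    from cordmap.pipeline import PipelineConfig, analyze_subject
    return analyze_subject(noisy_run, atlas, PipelineConfig(), "sub-01")
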