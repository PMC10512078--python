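import pytest

from neofusion import (
    AlignConfig,
    PlantedFusion,
    SampleMeta,
    TranscriptomeIndex,
    build_fusion_cdna_truth,
    generate_reference,
    simulate_sample,
)


@pytest.fixture(scope="session")
def toy_reference():
    return generate_reference(1, n_genes=4)


@pytest.fixture(scope="session")
def planted_fusion(toy_reference):
    return PlantedFusion("GENE2", 1, "GENE3", 2, 0.3)


@pytest.fixture(scope="session")
def fusion_truth(toy_reference, planted_fusion):
    return build_fusion_cdna_truth(toy_reference, planted_fusion)


@pytest.fixture(scope="session")
def align_cfg():
    return AlignConfig()


@pytest.fixture(scope="session")
def index(toy_reference, align_cfg):
    return TranscriptomeIndex.from_reference(toy_reference, align_cfg)


@pytest.fixture(scope="session")
def tumor_sample(toy_reference, planted_fusion):
    """Error-free sample carrying the planted fusion."""
    meta = SampleMeta("S01", "TNBC", True)
    return simulate_sample(
        toy_reference, [planted_fusion], meta, 2000, error_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def study_table():
    from neofusion import study_binding_table

    return study_binding_table()
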