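import pytest

from mitorearr.synthetic import GeneratorSpec, PlantedEvent, generate_mitogenome, plant_rearrangement


@pytest.fixture(scope="session")
def ancestral_record():
    record, truth = generate_mitogenome(GeneratorSpec(seed=1))
    return record, truth


@pytest.fixture(scope="session")
def derived_record(ancestral_record):
    record, _ = ancestral_record
    derived, truth = plant_rearrangement(record, PlantedEvent(), seed=101)
    return derived, truth
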