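import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_resources():
    from farmaner import make_fixture_resources
    return make_fixture_resources()


@pytest.fixture(scope="session")
def empty_code_map():
    from farmaner import TrainingCodeMap
    return TrainingCodeMap({})


@pytest.fixture()
def sample_document():
    from farmaner import AnnotatedDocument, EntityMention
    text = ("La glucosa estaba elevada. Se determino la citoqueratina "
            "en la biopsia.")
    doc = AnnotatedDocument("caso-01", text, [
        EntityMention("caso-01", "NORMALIZABLES", 3, 10, "glucosa",
                      code="67079006"),
        EntityMention("caso-01", "PROTEINAS", 43, 56, "citoqueratina"),
    ])
    doc.validate()
    return doc
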