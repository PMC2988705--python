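import pytest
from hypothesis import HealthCheck, settings

from termmap.model import Concept, SourceAtom, VocabularyView
from termmap.textnorm import EquivalenceTable

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_concept(cid, *terms, category=None, parents=(), source="SNOMEDCT"):
    """Concept with the first term preferred and the rest as synonyms."""
    atoms = [SourceAtom(cid, terms[0], "PT", source)]
    atoms += [SourceAtom(cid, t, "SY", source) for t in terms[1:]]
    return Concept(
        concept_id=cid,
        preferred_term=terms[0],
        terms=atoms,
        source=source,
        category=category,
        parent_ids=tuple(parents),
    )


def make_view(*concepts, source="SNOMEDCT"):
    return VocabularyView(source, concepts)


@pytest.fixture(scope="session")
def equivalences():
    return EquivalenceTable.default()


@pytest.fixture()
def lab_qualifier_view():
    """Tiny vocabulary for composition tests: lab test + qualifiers."""
    return make_view(
        make_concept("S001", "hematocrit", category="LAB_TEST"),
        make_concept("S002", "abnormal", category="QUALIFIER"),
        make_concept("S003", "hematocrit low", category="LAB_TEST"),
        make_concept("S004", "escherichia", category="ORGANISM"),
        make_concept("S005", "sepsis", category="OTHER"),
    )
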