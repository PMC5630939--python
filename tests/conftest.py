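import random

import pytest

from belflow.bel_core import (
    AnnotationSet,
    BelDocument,
    Evidence,
    StatementBlock,
    parse_statement,
)
from belflow.fixtures import GeneratorConfig, bundled_dictionaries, generate_corpus

# the two published annotations of the same CYP4A11 evidence sentence:
# the semi-automated (direct) and the manual (nested, secretion-mediated) form
SEMI_AUTOMATED_STATEMENT = "p(HGNC:CYP4A11) -> bp(GOBP:angiogenesis)"
MANUAL_STATEMENT = (
    "p(HGNC:CYP4A11) -> (sec(a(CHEBI:'20-HETE')) -> bp(GOBP:'blood vessel development'))"
)
# canonical serialization: 20-HETE needs no quotes ([A-Za-z0-9_-] only)
MANUAL_CANONICAL = (
    "p(HGNC:CYP4A11) -> (sec(a(CHEBI:20-HETE)) -> bp(GOBP:'blood vessel development'))"
)
EVIDENCE_SENTENCE = (
    "capillary vessel counting in and around primary tumors showed that CYP4A11 "
    "transfection significantly increased microvessel density per high-powered "
    "fields (HPF) (34.1 ± 7.3/HPF in control and 35.32 ± 6.4/HPF in GFP group vs. "
    "63.8 ± 11.4/HPF in A549-CYP4A11 group, P < 0.05)"
)


@pytest.fixture(scope="session")
def dictionaries():
    return bundled_dictionaries()


@pytest.fixture(scope="session")
def clean_corpus():
    return generate_corpus(GeneratorConfig(seed=11))


@pytest.fixture()
def rng():
    return random.Random(20240901)


def make_document(
    statement_texts,
    name="test document",
    pmid="21120482",
    evidence_text=EVIDENCE_SENTENCE,
):
    """A validated document holding the given statement texts, one block."""
    statements = tuple(parse_statement(t) for t in statement_texts)
    doc = BelDocument(
        name=name,
        namespaces={
            "HGNC": "https://www.genenames.org",
            "GOBP": "http://www.geneontology.org",
            "CHEBI": "https://www.ebi.ac.uk/chebi",
            "SCHEM": "https://www.openbel.org/schem",
            "MESHD": "https://www.nlm.nih.gov/mesh",
        },
        annotation_definitions={"Species": "taxonomy"},
        blocks=[
            StatementBlock(
                Evidence(evidence_text, pmid, "results"),
                AnnotationSet.from_dict({"Species": "10090"}),
                statements,
            )
        ],
    )
    return doc


@pytest.fixture()
def worked_example_document():
    return make_document([SEMI_AUTOMATED_STATEMENT, MANUAL_STATEMENT])
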