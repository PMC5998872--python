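import numpy as np
import pandas as pd
import pytest

from celldecon import (
    ExpressionMatrix,
    GeneratorSpec,
    PhenotypeAnnotation,
    generate_mixtures,
    generate_references,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two classes of two replicates."""
    data = pd.DataFrame(
        {
            "a1": [10.0, 1.0, 5.0],
            "a2": [12.0, 1.2, 5.5],
            "b1": [1.0, 9.0, 5.0],
            "b2": [1.1, 11.0, 5.2],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_annotation() -> PhenotypeAnnotation:
    return PhenotypeAnnotation({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture(scope="session")
def study_spec() -> GeneratorSpec:
    """The default study conditions: 8 classes, 1000 genes, 5 markers per
    class, 3 replicates, 1% log2-scale noise, 50 flat-Dirichlet mixtures."""
    return GeneratorSpec(seed=20240901)


@pytest.fixture(scope="session")
def study_data(study_spec):
    refs, annotation = generate_references(study_spec)
    mixtures, truth = generate_mixtures(refs, annotation, study_spec)
    return refs, annotation, mixtures, truth
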