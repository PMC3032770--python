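"""Shared fixtures: the packaged reference annotation and synthetic datasets.

Everything is generated programmatically at test time; the only files read
are the small TSV tables shipped inside the package.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitocistron.datasets import (
    load_codon_counts,
    load_expression_profile,
    load_mitogenome_annotation,
)
from mitocistron.simulate import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def table2():
    """The packaged 34-feature mitogenome annotation."""
    return load_mitogenome_annotation()


@pytest.fixture(scope="session")
def table3():
    return load_codon_counts()


@pytest.fixture(scope="session")
def table4():
    return load_expression_profile()


@pytest.fixture(scope="session")
def synth():
    """(genome, annotation, manifest) realizing the reference layout."""
    return generate_genome(GenomeSpec.table2(seed=20))


@pytest.fixture(scope="session")
def synth_genome(synth):
    return synth[0]


@pytest.fixture(scope="session")
def synth_annotation(synth):
    return synth[1]
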