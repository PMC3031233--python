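import numpy as np
import pytest

from agerepair.data import (
    CLASS_NEGATIVE,
    CLASS_POSITIVE,
    AttributeDescriptor,
    make_dataset,
)
from agerepair.features import build_dataset
from agerepair.ontology import load_obo
from agerepair.simulate import GeneratorConfig, generate_cohort


DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: top
namespace: biological_process

[Term]
id: GO:0000002
name: left
namespace: biological_process
is_a: GO:0000001 ! top

[Term]
id: GO:0000003
name: right
namespace: biological_process
is_a: GO:0000001 ! top

[Term]
id: GO:0000004
name: bottom
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000002 ! left
is_a: GO:0000003 ! right

[Term]
id: GO:0000005
name: retired
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def diamond_graph(tmp_path):
    """Four-term diamond (D is_a B,C; B,C is_a A) plus one obsolete term."""
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return load_obo(path)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (140 genes, 33 positives), seed 1."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def d5_dataset(cohort):
    return build_dataset(
        cohort.records, cohort.interactions, cohort.ontology, t=3, variant="D5"
    )


@pytest.fixture(scope="session")
def d1_dataset(cohort):
    return build_dataset(
        cohort.records, cohort.interactions, cohort.ontology, t=3, variant="D1"
    )


def toy_dataset(rows, kinds, classes, domains=None):
    """Small hand-built dataset; kinds maps attribute name -> kind."""
    domains = domains or {}
    attrs = [
        AttributeDescriptor(name, kind, domains.get(name))
        for name, kind in kinds.items()
    ]
    ids = [f"g{i}" for i in range(len(rows))]
    return make_dataset(ids, attrs, rows, classes)


def random_mixed_dataset(rng, n, n_binary=3, n_numeric=2, missing_rate=0.0):
    """Random small dataset mixing binary and numeric attributes."""
    kinds = {}
    rows = [dict() for _ in range(n)]
    for b in range(n_binary):
        name = f"b{b}"
        kinds[name] = "binary"
        for r in rows:
            r[name] = "yes" if rng.random() < 0.5 else "no"
    for m in range(n_numeric):
        name = f"x{m}"
        kinds[name] = "numeric"
        for r in rows:
            r[name] = float(np.round(rng.normal(), 3))
    if missing_rate:
        for r in rows:
            for name in kinds:
                if rng.random() < missing_rate:
                    r[name] = None
    classes = [
        CLASS_POSITIVE if rng.random() < 0.4 else CLASS_NEGATIVE for _ in range(n)
    ]
    # guarantee both classes
    classes[0] = CLASS_POSITIVE
    classes[1] = CLASS_NEGATIVE
    return toy_dataset(rows, kinds, classes)
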