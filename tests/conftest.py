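"""Shared fixtures: toy taxonomy dumps, toy references, random collections."""

from __future__ import annotations

import numpy as np
import pytest

from cedarquant.eqclass import ClassCollection, EquivalenceClass
from cedarquant.references import ReferenceSet

NODES_DMP = """\
1\t|\t1\t|\troot\t|
10\t|\t1\t|\tgenus\t|
101\t|\t10\t|\tspecies\t|
102\t|\t10\t|\tspecies\t|
20\t|\t1\t|\tgenus\t|
201\t|\t20\t|\tspecies\t|
7\t|\t99\t|\tspecies\t|
"""

NAMES_DMP = """\
1\t|\tcellular organisms\t|\t\t|\tscientific name\t|
10\t|\tToygenus\t|\t\t|\tscientific name\t|
101\t|\tToyspecies one\t|\t\t|\tscientific name\t|
101\t|\tT. uno\t|\t\t|\tsynonym\t|
102\t|\tToyspecies two\t|\t\t|\tscientific name\t|
20\t|\tOthergenus\t|\t\t|\tscientific name\t|
201\t|\tOtherspecies\t|\t\t|\tscientific name\t|
7\t|\tBroken lineage sp.\t|\t\t|\tscientific name\t|
"""


@pytest.fixture
def taxonomy_files(tmp_path):
    nodes = tmp_path / "nodes.dmp"
    names = tmp_path / "names.dmp"
    nodes.write_text(NODES_DMP)
    names.write_text(NAMES_DMP)
    return nodes, names


@pytest.fixture
def toy_db(taxonomy_files):
    from cedarquant.taxonomy import load_taxonomy

    return load_taxonomy(*taxonomy_files)


def make_refs(ids, length=10000):
    return ReferenceSet(ids=list(ids), lengths=np.full(len(ids), length))


def random_collection(rng: np.random.Generator, max_refs: int = 12, max_classes: int = 20):
    """A random equivalence-class collection for engine property tests.

    Labels are random non-empty reference subsets; weights are positive with
    the best reference at 1; counts are small positive integers. Duplicate
    (label, signature) pairs are merged by construction of the dict.
    """
    n_refs = int(rng.integers(3, max_refs + 1))
    refs = make_refs([f"R{i:02d}" for i in range(n_refs)], length=int(rng.integers(2000, 20000)))
    n_classes = int(rng.integers(3, max_classes + 1))
    seen: dict[tuple, EquivalenceClass] = {}
    for _ in range(n_classes):
        size = int(rng.integers(1, min(4, n_refs) + 1))
        label = tuple(sorted(rng.choice(n_refs, size=size, replace=False).tolist()))
        if label in seen:
            continue
        w = rng.uniform(0.05, 1.0, size=len(label))
        w[rng.integers(len(label))] = 1.0
        seen[label] = EquivalenceClass(
            label=label,
            count=int(rng.integers(1, 51)),
            weights=w,
            bin_signature=(0,) * len(label),
        )
    classes = list(seen.values())
    if not classes:
        classes = [EquivalenceClass(label=(0,), count=5, weights=np.ones(1), bin_signature=(0,))]
    return ClassCollection(classes=classes, refs=refs)


@pytest.fixture
def fig2_collection():
    """Reconstruction of the worked six-genome example: G1 with 2 unique
    reads, G2/G3 well covered, and a fully shared multi-mapping island
    {G4, G5, G6} holding 3 reads."""
    refs = make_refs([f"G{i}" for i in range(1, 7)])
    classes = [
        EquivalenceClass((0,), 2, np.ones(1), (0,)),
        EquivalenceClass((1,), 100, np.ones(1), (0,)),
        EquivalenceClass((2,), 100, np.ones(1), (0,)),
        EquivalenceClass((3, 4, 5), 3, np.ones(3), (0, 0, 0)),
    ]
    return ClassCollection(classes=classes, refs=refs)
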