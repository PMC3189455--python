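"""Shared fixtures: small synthetic corpora, traces and trained potentials.

Everything is generated programmatically with fixed seeds; session scope
keeps the heavier fixtures (potential training, tessellations) to one
computation per test run.
"""

import numpy as np
import pytest

from fourbody import (
    CAlphaTrace,
    ResiduePoint,
    SyntheticSpec,
    generate_corpus,
    generate_trace,
    tessellate,
    train_potential,
)


@pytest.fixture(scope="session")
def corpus():
    """10 self-avoiding-walk structures of 50 residues, uniform composition."""
    return generate_corpus(SyntheticSpec(n_residues=50, n_structures=10, seed=11))


@pytest.fixture(scope="session")
def table(corpus):
    """Four-body potential trained on the session corpus."""
    return train_potential((tessellate(t), t) for t in corpus)


@pytest.fixture(scope="session")
def target_trace():
    """A 60-residue wild-type structure, independent of the corpus."""
    return generate_trace(SyntheticSpec(n_residues=60, seed=42))


@pytest.fixture(scope="session")
def target_tess(target_trace):
    return tessellate(target_trace)


@pytest.fixture()
def single_simplex():
    """A 4-residue structure (types A, C, D, E) forming one tetrahedron."""
    pts = np.array([[0, 0, 0], [3.8, 0, 0], [1.9, 3.3, 0], [1.9, 1.1, 3.1]], float)
    residues = [
        ResiduePoint(i + 1, str(i + 1), aa, pts[i]) for i, aa in enumerate("ACDE")
    ]
    return CAlphaTrace(chain_id="A", residues=residues, source_id="tetra")


def make_trace(coords, sequence, chain_id="A", source_id="synthetic"):
    """Build a trace from raw coordinates and a one-letter sequence."""
    coords = np.asarray(coords, float)
    residues = [
        ResiduePoint(i + 1, str(i + 1), aa, coords[i])
        for i, aa in enumerate(sequence)
    ]
    return CAlphaTrace(chain_id=chain_id, residues=residues, source_id=source_id)
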