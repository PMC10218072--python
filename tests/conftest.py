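"""Shared fixtures: synthetic study panels and a hand-built toy matrix."""

import numpy as np
import pytest

from dtpics import (
    GenotypeMatrix,
    Locus,
    SelectionConfig,
    SynthConfig,
    dtpics_select,
    generate_panel,
)

#: Seed for the main study panel used across tests.
PANEL_SEED = 101
#: Seed for the marker selection on that panel.
SELECT_SEED = 42


@pytest.fixture(scope="session")
def panel200():
    """200 varieties x 5000 biallelic loci, all pairwise distinct."""
    config = SynthConfig(n_varieties=200, n_loci=5000, seed=PANEL_SEED)
    matrix, truth = generate_panel(config)
    return matrix


@pytest.fixture(scope="session")
def sets200(panel200):
    """Two disjoint simplified marker sets selected on the study panel."""
    return dtpics_select(panel200, SelectionConfig(n_sets=2, seed=SELECT_SEED))


@pytest.fixture(scope="session")
def small_panel():
    """A fast panel for unit-level checks."""
    matrix, _ = generate_panel(SynthConfig(n_varieties=60, n_loci=900, seed=7))
    return matrix


def _binary_matrix(samples, columns):
    """Build a biallelic homozygous matrix from 0/1 column tuples."""
    n = len(samples)
    loci = []
    calls = np.zeros((n, len(columns)), dtype=np.int16)
    code_labels = []
    for j, (name, col) in enumerate(columns):
        assert len(col) == n
        loci.append(Locus(name, "1", 100 * (j + 1), ("A", "T")))
        calls[:, j] = col
        code_labels.append({0: "A/A", 1: "T/T"})
    return GenotypeMatrix(samples, loci, calls, code_labels)


@pytest.fixture()
def toy8x7():
    """Eight varieties, seven SNPs; SNP2 is redundant given SNP1/3/4.

    SNP1 halves the panel, SNP2/SNP3/SNP4 refine it; {SNP1, SNP3, SNP4}
    distinguishes all eight varieties, so a correct pruning pass must shrink
    the screened set {SNP1..SNP4} to three markers.  SNP5-7 are low-PIC
    fillers.
    """
    return _binary_matrix(
        [f"V{i}" for i in range(1, 9)],
        [
            ("SNP1", (0, 0, 0, 0, 1, 1, 1, 1)),
            ("SNP2", (0, 0, 1, 1, 0, 0, 1, 1)),
            ("SNP3", (0, 1, 0, 1, 0, 1, 0, 1)),
            ("SNP4", (0, 0, 1, 1, 1, 1, 0, 0)),
            ("SNP5", (0, 0, 0, 0, 0, 0, 0, 1)),
            ("SNP6", (1, 0, 0, 0, 0, 0, 0, 0)),
            ("SNP7", (0, 0, 0, 1, 0, 0, 0, 0)),
        ],
    )


@pytest.fixture()
def make_binary_matrix():
    """Factory for small hand-specified biallelic matrices."""
    return _binary_matrix
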