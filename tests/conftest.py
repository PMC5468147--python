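import numpy as np
import pytest

from mitoselect import (
    AnnotatedAlignment,
    GeneModel,
    SimulationConfig,
    simulate_alignment,
)

BASES = "TCAG"
# NCBI translation table 2 amino acids in TCAG codon order, frozen by hand
_TABLE2_AAS = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"


def table2_oracle() -> dict[str, str]:
    """Independent hand-frozen vertebrate mitochondrial code, all 64 codons."""
    codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    return dict(zip(codons, _TABLE2_AAS))


def make_alignment(seqs, genes, pools=None):
    """Small AnnotatedAlignment from a list of sequences (auto-named s0, s1, ...)."""
    sequences = {f"s{i}": s for i, s in enumerate(seqs)}
    if pools is None:
        pools = {name: "poolA" for name in sequences}
    return AnnotatedAlignment(sequences=sequences, pools=pools, genes=genes)


@pytest.fixture(scope="session")
def sim_default():
    """Full-scale synthetic study at the emulated design's default targets."""
    return simulate_alignment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def table2():
    return table2_oracle()
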