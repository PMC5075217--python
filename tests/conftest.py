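import numpy as np
import pytest

from ampcnv.panel import Amplicon, AmpliconPanel
from ampcnv.simulate import SimulationParams, default_panel, random_events, simulate


@pytest.fixture(scope="session")
def panel130():
    """The simulator's default 3-gene, 130-amplicon panel."""
    return default_panel()


@pytest.fixture(scope="session")
def null_run(panel130):
    """One CNV-free simulated run (48 samples) shared across tests."""
    return simulate(SimulationParams(panel=panel130, seed=1234))


@pytest.fixture(scope="session")
def cnv_run(panel130):
    """One simulated run with four CNV carriers plus its truth set."""
    samples = [f"S{i + 1:02d}" for i in range(48)]
    rng = np.random.default_rng(7)
    events = random_events(panel130, samples, 4, rng)
    matrix, truth = simulate(SimulationParams(panel=panel130, cnv_events=events,
                                              seed=4321))
    return matrix, truth


def make_panel(spec):
    """Build a panel from (id, chrom, start, end, gene, site) tuples."""
    return AmpliconPanel([Amplicon(i, c, s, e, g, x) for i, c, s, e, g, x in spec])


@pytest.fixture
def tiny_panel():
    return make_panel([
        ("a1", "chr1", 100, 300, "GENE1", "GENE1_ex1"),
        ("a2", "chr1", 400, 600, "GENE1", "GENE1_ex1"),
        ("a3", "chr1", 700, 900, "GENE1", "GENE1_ex2"),
        ("b1", "chr2", 100, 300, "GENE2", "GENE2_ex1"),
        ("b2", "chr2", 400, 600, "GENE2", "GENE2_ex1"),
    ])
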