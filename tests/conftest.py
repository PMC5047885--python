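import dataclasses

import pytest

from synkaryo.genome_model import Gene, GenomePanel
from synkaryo.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def tiny_panels():
    """Two three-gene chromosomes forming a perfect diagonal."""
    pa = GenomePanel(
        "A",
        [Gene(f"a{i}", "chrA1", 100 * i + 1, 100 * i + 50, "+") for i in range(3)],
    )
    pb = GenomePanel(
        "B",
        [Gene(f"b{i}", "chrB1", 100 * i + 1, 100 * i + 50, "+") for i in range(3)],
    )
    return pa, pb


@pytest.fixture(scope="session")
def wgd_sim():
    """A seeded WGD + fusion simulation shared by read-only tests."""
    cfg = SimulationConfig(
        seed=42,
        ancestral_chromosomes=2,
        genes_per_chromosome=60,
        codons_per_gene=120,
        wgd_in_lineage_b=True,
        fusion_events=[("chr1a", "chr2a")],
        per_copy_loss_rate=0.3,
        ks_split=1.05,
        ks_wgd=0.6,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def lossless_sim():
    """WGD, no gene loss: every query gene keeps both subject copies."""
    cfg = SimulationConfig(
        seed=7,
        ancestral_chromosomes=2,
        genes_per_chromosome=50,
        codons_per_gene=100,
        wgd_in_lineage_b=True,
        per_copy_loss_rate=0.0,
        ks_split=1.05,
        ks_wgd=0.6,
    )
    return simulate(cfg)
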