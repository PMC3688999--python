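import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plastocomp import synthetic_data as syn


@pytest.fixture(scope="session")
def mid_plastome():
    """34-kb quadripartite genome with introns, IR genes and ground truth."""
    spec = syn.PlastomeSpec(lsc_len=20_000, ssc_len=6_000, ir_len=4_000,
                            n_genes=30, n_trna=8, intron_genes=3, ir_genes=1,
                            seed=1)
    return syn.make_plastome(spec)


@pytest.fixture(scope="session")
def planted_pair(mid_plastome):
    """Genome pair with 7 shared + 4 unique planted SSRs and 2% background
    spacer divergence."""
    genome, truth = mid_plastome
    specs = [
        syn.PlantedSSRSpec("A", 12), syn.PlantedSSRSpec("AT", 6),
        syn.PlantedSSRSpec("AAG", 5, "coding"),
        syn.PlantedSSRSpec("T", 11, "intron"),
        syn.PlantedSSRSpec("GA", 7), syn.PlantedSSRSpec("C", 10),
        syn.PlantedSSRSpec("ATC", 4),
        syn.PlantedSSRSpec("A", 14, shared=False),
        syn.PlantedSSRSpec("CT", 6, shared=False),
        syn.PlantedSSRSpec("G", 10, "coding", shared=False),
        syn.PlantedSSRSpec("TTA", 4, shared=False),
    ]
    ga, gb, ptruth = syn.make_genome_pair(
        genome, truth, syn.DivergenceSpec(default_rate=0.02), specs, seed=7)
    return ga, gb, truth, ptruth
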