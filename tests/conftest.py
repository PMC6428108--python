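import numpy as np
import pandas as pd
import pytest

from apakit import CONDITIONS, SimConfig, build_genome, call_pa_sites, \
    make_gene_models, simulate_paseq_reads
from apakit.genome import ArrayGenome


def genome_from_str(chrom: str, seq: str) -> ArrayGenome:
    return ArrayGenome({chrom: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()})


@pytest.fixture(scope="session")
def small_study():
    """A 30-gene simulated study with genome, reads and called clusters."""
    cfg = SimConfig(n_genes=30, seed=7, ip_decoy_frac=0.2, jitter_sd=2)
    genes, truth = make_gene_models(cfg)
    genome = build_genome(truth, cfg)
    reads = pd.concat(
        [simulate_paseq_reads(truth, cfg, c) for c in CONDITIONS],
        ignore_index=True)
    clusters, counts = call_pa_sites(reads, genes, genome=genome)
    return {"config": cfg, "genes": genes, "truth": truth, "genome": genome,
            "reads": reads, "clusters": clusters, "counts": counts}
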