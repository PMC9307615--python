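import numpy as np
import pytest

from scvartools.genome_model import AnnotatedGenome, DepthTrack, GeneRecord, revcomp
from scvartools.synthetic_data import SimConfig, simulate


def _fill(seq: list, start: int, insert: str) -> None:
    seq[start : start + len(insert)] = list(insert)


@pytest.fixture(scope="session")
def toy_genome() -> AnnotatedGenome:
    """One 400 bp contig with two '+' CDS, one '-' CDS, and one rRNA gene.

    geneA  '+' [30, 69):   ATG GGA GAA AAA CCC TTT GCA GAT AAC CAT GGG TAG
    geneB  '-' [100, 139): same CDS on the minus strand
    geneC  '+' [200, 230): ATG GGT CAT TGG AAA CGT GAC GAA TTC TGA
    rrna1      [300, 350)
    """
    rng = np.random.default_rng(42)
    seq = list("".join(rng.choice(list("ACGT"), size=400)))
    cds_a = "ATGGGAGAAAAACCCTTTGCAGATAACCATGGGTAG"
    cds_c = "ATGGGTCATTGGAAACGTGACGAATTCTGA"
    _fill(seq, 30, cds_a)
    _fill(seq, 100, revcomp(cds_a))
    _fill(seq, 200, cds_c)
    genes = [
        GeneRecord("geneA", "c1", 30, 30 + len(cds_a), "+", "CDS", "protein A"),
        GeneRecord("geneB", "c1", 100, 100 + len(cds_a), "-", "CDS", "protein B"),
        GeneRecord("geneC", "c1", 200, 200 + len(cds_c), "+", "CDS", "protein C"),
        GeneRecord("rrna1", "c1", 300, 350, "+", "rRNA", "ribosomal RNA"),
    ]
    return AnnotatedGenome({"c1": "".join(seq)}, genes)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_contigs=2,
        contig_length=60_000,
        n_genes=30,
        mean_gene_length=600,
        hotspot_genes=4,
        hotspot_variants_per_gene=8,
        singleton_noise_rate=40.0,
        replicate_detection_prob=0.95,
        breadth_mean=0.85,
    )


@pytest.fixture(scope="session")
def sim_bundle(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return simulate(small_config, out_dir=out)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


@pytest.fixture()
def random_track(rng) -> DepthTrack:
    """Random RLE depth track over a 5000 bp contig."""
    runs = []
    cursor = 0
    while cursor < 5000:
        length = int(rng.integers(1, 400))
        depth = int(rng.integers(0, 6))
        end = min(cursor + length, 5000)
        if depth > 0:
            runs.append((cursor, end, depth))
        cursor = end
    return DepthTrack("r1", {"c1": np.array(runs, dtype=np.int64)})
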