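import numpy as np
import pytest

from phamkit import apply_pham_labels, build_phams
from phamkit.records import GeneRecord, GenomeRecord
from phamkit.synthetic import SimulationSpec, simulate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA), size=length - 1))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def toy_genome(genome_id: str, genes: list[tuple[str, int, int, str, str]],
               length: int = 0, circular: bool = False) -> GenomeRecord:
    """Build a genome whose sequence is arbitrary A-filler of the needed length."""
    need = max((end for _, _, end, _, _ in genes), default=0)
    length = max(length, need)
    records = [
        GeneRecord(gene_id=gid, genome_id=genome_id, start=s, end=e,
                   strand=st, translation=aa)
        for gid, s, e, st, aa in genes
    ]
    return GenomeRecord(genome_id=genome_id, sequence="A" * length,
                        circular=circular, genes=records)


def ungapped_local_oracle(query: str, subject: str) -> tuple[int, int, int, int]:
    """Quadratic-time ungapped local alignment oracle (+1 match, -2 mismatch).

    Scans every diagonal with a prefix-sum maximum-subarray search; forward
    strand only. Independent of the seed-and-extend implementation.
    Returns (q_start, q_end, matches, score) of the best segment.
    """
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    sa = np.frombuffer(subject.encode(), dtype=np.uint8)
    m, n = len(qa), len(sa)
    best = (0, 0, 0, -1)
    for d in range(-(n - 1), m):
        q0 = max(0, d)
        s0 = q0 - d
        length = min(m - q0, n - s0)
        if length <= 0:
            continue
        eq = qa[q0:q0 + length] == sa[s0:s0 + length]
        scores = np.where(eq, 1, -2)
        prefix = np.concatenate(([0], np.cumsum(scores)))
        min_prefix = np.minimum.accumulate(prefix[:-1])
        gains = prefix[1:] - min_prefix
        k = int(np.argmax(gains))
        score = int(gains[k])
        if score > best[3]:
            j = int(np.argmin(prefix[:k + 1]))
            match_prefix = np.concatenate(([0], np.cumsum(eq)))
            matches = int(match_prefix[k + 1] - match_prefix[j])
            best = (q0 + j, q0 + k + 1, matches, score)
    return best


@pytest.fixture(scope="session")
def small_dataset():
    """Two planted clusters of three genomes each, phams assembled."""
    spec = SimulationSpec(
        seed=7, n_clusters=2, genomes_per_cluster=3, phams_per_genome=12,
        gene_length_mean=140, gene_length_sd=25, hgt_rate=1.0,
    )
    genomes, truth = simulate_dataset(spec)
    genes = [g for gm in genomes for g in gm.genes]
    phams = build_phams(genes)
    apply_pham_labels(genomes, phams)
    return genomes, phams, truth
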