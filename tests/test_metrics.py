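"""Pairwise similarity metrics: GCS, AAI, PEQ, HSP search, gNI."""

import numpy as np
import pytest

from phamkit.metrics import (
    SimilarityMatrix,
    aai_shared,
    find_hsps,
    gcs,
    gni,
    pairwise_matrix,
    peq,
)
from phamkit.records import GeneRecord, GenomeRecord
from phamkit.seqio import reverse_complement
from phamkit.synthetic import mutate_sequence

from conftest import AA, random_dna, random_protein, ungapped_local_oracle


def _proteome(genome_id: str, proteins: dict[str, str]) -> GenomeRecord:
    """Genome whose sequence content is irrelevant; genes laid end to end."""
    genes, pos = [], 0
    for gid, seq in proteins.items():
        nt_len = 3 * (len(seq) + 1)
        genes.append(GeneRecord(gene_id=gid, genome_id=genome_id, start=pos,
                                end=pos + nt_len, strand="+", translation=seq))
        pos += nt_len
    return GenomeRecord(genome_id, "A" * pos, genes=genes)


# ---------------------------------------------------------------------------
# GCS / AAI / PEQ
# ---------------------------------------------------------------------------

def _rng_proteins(n, length=60, seed=0):
    rng = np.random.default_rng(seed)
    return [random_protein(rng, length) for _ in range(n)]


def test_gcs_identical_and_disjoint():
    p = _rng_proteins(3)
    a = _proteome("a", {f"g{i}": s for i, s in enumerate(p)})
    b = _proteome("b", {f"g{i}": s for i, s in enumerate(p)})
    table = {("a", f"g{i}"): str(i) for i in range(3)}
    table |= {("b", f"g{i}"): str(i) for i in range(3)}
    assert gcs(a, b, table) == 100.0
    disjoint = {("a", f"g{i}"): str(i) for i in range(3)}
    disjoint |= {("b", f"g{i}"): str(i + 10) for i in range(3)}
    assert gcs(a, b, disjoint) == 0.0


def test_gcs_sixty_percent_shared():
    """Two five-gene genomes sharing three phams: GCS = 60."""
    p = _rng_proteins(10)
    a = _proteome("a", {f"g{i}": p[i] for i in range(5)})
    b = _proteome("b", {f"g{i}": p[i + 5] for i in range(5)})
    table = {("a", f"g{i}"): f"p{i}" for i in range(5)}
    # b shares phams p0..p2, has its own p10, p11
    table |= {("b", "g0"): "p0", ("b", "g1"): "p1", ("b", "g2"): "p2",
              ("b", "g3"): "p10", ("b", "g4"): "p11"}
    assert gcs(a, b, table) == pytest.approx(60.0)


def test_gcs_requires_pham_assignments():
    p = _rng_proteins(2)
    a = _proteome("a", {"g0": p[0]})
    b = _proteome("b", {"g0": p[1]})
    with pytest.raises(ValueError):
        gcs(a, b, {("a", "g0"): "p0"})  # b has no assigned genes


def test_aai_identical_and_none_shared():
    p = _rng_proteins(4)
    a = _proteome("a", {"g0": p[0], "g1": p[1]})
    b = _proteome("b", {"g0": p[0], "g1": p[1]})
    table = {(g, f"g{i}"): f"p{i}" for g in "ab" for i in range(2)}
    aai, weight = aai_shared(a, b, table)
    assert aai == pytest.approx(100.0)
    assert weight == 2 * (len(p[0]) + len(p[1]))
    disjoint = {("a", "g0"): "x0", ("a", "g1"): "x1",
                ("b", "g0"): "y0", ("b", "g1"): "y1"}
    assert aai_shared(a, b, disjoint) == (0.0, 0)


def test_aai_one_shared_pham_eighty_percent():
    rng = np.random.default_rng(5)
    x = random_protein(rng, 100)
    y = list(x)
    for i in rng.choice(100, size=20, replace=False):
        y[i] = next(c for c in AA if c != x[i])
    a = _proteome("a", {"g0": x})
    b = _proteome("b", {"g0": "".join(y)})
    table = {("a", "g0"): "p", ("b", "g0"): "p"}
    aai, _ = aai_shared(a, b, table)
    assert aai == pytest.approx(80.0, abs=1.0)


def test_peq_hand_computed_example():
    """Two 2-gene genomes of 100-aa proteins, one shared pham at 90%:
    PEQ = 100 * (200 * 0.9) / 400 = 45."""
    rng = np.random.default_rng(6)
    x = random_protein(rng, 100)
    y = list(x)
    for i in rng.choice(100, size=10, replace=False):
        y[i] = next(c for c in AA if c != x[i])
    a = _proteome("a", {"g0": x, "g1": random_protein(rng, 100)})
    b = _proteome("b", {"g0": "".join(y), "g1": random_protein(rng, 100)})
    table = {("a", "g0"): "p", ("b", "g0"): "p",
             ("a", "g1"): "ua", ("b", "g1"): "ub"}
    assert peq(a, b, table) == pytest.approx(45.0, abs=1.0)


def test_peq_extremes_and_bound(small_dataset):
    genomes, phams, _ = small_dataset
    a, b = genomes[0], genomes[1]
    assert peq(a, a) == pytest.approx(100.0)
    total = sum(g.length_aa for g in a.genes) + sum(g.length_aa for g in b.genes)
    _, shared_weight = aai_shared(a, b)
    assert peq(a, b) <= 100.0 * shared_weight / total + 1e-9


# ---------------------------------------------------------------------------
# find_hsps
# ---------------------------------------------------------------------------

def test_self_hit_full_length():
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 10_000)
    hsps = find_hsps(seq, seq)
    top = hsps[0]
    assert (top.q_start, top.q_end) == (0, 10_000)
    assert (top.s_start, top.s_end) == (0, 10_000)
    assert top.identities == 10_000
    assert top.strand == "+"


def test_reverse_complement_hit():
    rng = np.random.default_rng(8)
    seq = random_dna(rng, 5_000)
    hsps = find_hsps(seq, reverse_complement(seq))
    top = hsps[0]
    assert top.strand == "-"
    assert (top.q_start, top.q_end) == (0, 5_000)
    assert top.identities == 5_000


def test_word_size_floor_and_short_sequence():
    with pytest.raises(ValueError):
        find_hsps("ACGTACGTACGT", "ACGTACGTACGT", word_size=5)
    with pytest.raises(ValueError):
        find_hsps("ACGT", "ACGTACGTACGTACG")


def test_planted_segment_recovered_against_oracle():
    """A 500-bp shared segment inside otherwise-random 10-kbp sequences is
    recovered with endpoints within one word of the quadratic oracle."""
    rng = np.random.default_rng(9)
    segment = random_dna(rng, 500)
    q = random_dna(rng, 4_000) + segment + random_dna(rng, 1_500)
    s = random_dna(rng, 1_000) + segment + random_dna(rng, 3_000)
    hsps = [h for h in find_hsps(q, s) if h.strand == "+"]
    top = max(hsps, key=lambda h: h.score)
    oq0, oq1, omatches, _ = ungapped_local_oracle(q, s)
    assert abs(top.q_start - oq0) <= 11
    assert abs(top.q_end - oq1) <= 11
    assert top.identities >= 0.98 * omatches


def test_evalue_filter_blocks_weak_hits():
    rng = np.random.default_rng(10)
    q, s = random_dna(rng, 3_000), random_dna(rng, 3_000)
    assert find_hsps(q, s, evalue_max=1e-4) == []


# ---------------------------------------------------------------------------
# gNI
# ---------------------------------------------------------------------------

def test_gni_identical_sequences():
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 8_000)
    a = GenomeRecord("a", seq)
    b = GenomeRecord("b", seq)
    assert gni(a, b) == pytest.approx(100.0)


def test_gni_unrelated_pair_is_zero():
    rng = np.random.default_rng(12)
    a = GenomeRecord("a", random_dna(rng, 20_000))
    b = GenomeRecord("b", random_dna(rng, 20_000))
    # oracle: no HSP at all passes the E-value gate in either role
    assert find_hsps(a.sequence, b.sequence) == []
    assert find_hsps(b.sequence, a.sequence) == []
    assert gni(a, b) == 0.0


def test_gni_symmetry_and_partial_similarity():
    rng = np.random.default_rng(13)
    shared = random_dna(rng, 5_000)
    a = GenomeRecord("a", shared + random_dna(rng, 5_000))
    b = GenomeRecord("b", random_dna(rng, 5_000) + shared)
    ab, ba = gni(a, b), gni(b, a)
    assert ab == pytest.approx(ba, abs=1e-9)
    assert ab == pytest.approx(50.0, abs=2.0)
    with pytest.raises(ValueError):
        gni(GenomeRecord("x", ""), a)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def test_matrix_identical_genomes():
    rng = np.random.default_rng(14)
    seq = random_dna(rng, 3_000)
    gs = [GenomeRecord(f"g{i}", seq) for i in range(3)]
    mat = pairwise_matrix(gs, "gni")
    assert np.allclose(mat.values, 100.0)


def test_matrix_matches_pairwise_recomputation(small_dataset):
    genomes, phams, _ = small_dataset
    subset = genomes[:4]
    mat = pairwise_matrix(subset, "peq", phams=phams)
    assert np.allclose(mat.values, mat.values.T)
    for i, a in enumerate(subset):
        for j, b in enumerate(subset):
            expected = 100.0 if i == j else peq(a, b)
            assert mat.values[i, j] == pytest.approx(expected)


def test_matrix_rejects_duplicate_ids():
    rng = np.random.default_rng(15)
    seq = random_dna(rng, 1_000)
    with pytest.raises(ValueError):
        pairwise_matrix([GenomeRecord("g", seq), GenomeRecord("g", seq)], "gni")


def test_matrix_validation_and_tsv_round_trip(tmp_path):
    vals = np.array([[100.0, 42.5], [42.5, 100.0]])
    mat = SimilarityMatrix(["a", "b"], vals, metric="peq")
    path = tmp_path / "m.tsv"
    mat.write_square_tsv(str(path))
    back = SimilarityMatrix.read_square_tsv(str(path))
    assert back.ids == ["a", "b"]
    assert np.allclose(back.values, vals)
    with pytest.raises(ValueError):
        SimilarityMatrix(["a", "b"], np.array([[100.0, 2.0], [3.0, 100.0]]))
    with pytest.raises(ValueError):
        SimilarityMatrix(["a", "b"], np.array([[90.0, 2.0], [2.0, 100.0]]))
    with pytest.raises(ValueError):
        SimilarityMatrix(["a", "b"], np.array([[100.0, 101.0], [101.0, 100.0]]))
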