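"""Genome I/O, ORF calling, and circular reorientation."""

import numpy as np
import pytest

from phamkit.records import GeneRecord, GenomeRecord
from phamkit.seqio import (
    FeatureError,
    SequenceAlphabetError,
    call_orfs,
    read_genome,
    reorient_circular,
    reverse_complement,
    translate_cds,
    write_fasta,
    write_genbank,
    write_gff3,
)

from conftest import random_dna

GENBANK_TWO_CDS = """\
LOCUS       ToyPhage                  60 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  toy.
ACCESSION   ToyPhage
FEATURES             Location/Qualifiers
     CDS             5..13
                     /locus_tag="gp1"
                     /translation="MK"
     CDS             21..29
                     /locus_tag="gp2"
                     /translation="MT"
ORIGIN
        1 acgtatgaaa taagacacta atgacttaag acgtacgtac gtacgtacgt acgtacgtac
//
"""


def test_genbank_coordinates_shift_to_zero_based(tmp_path):
    """1-based inclusive GenBank CDS locations become 0-based half-open."""
    path = tmp_path / "toy.gbk"
    path.write_text(GENBANK_TWO_CDS)
    g = read_genome(str(path), fmt="genbank")
    assert [gene.gene_id for gene in g.genes] == ["gp1", "gp2"]
    assert (g.genes[0].start, g.genes[0].end) == (4, 13)
    assert (g.genes[1].start, g.genes[1].end) == (20, 29)
    assert [gene.strand for gene in g.genes] == ["+", "+"]
    assert [gene.translation for gene in g.genes] == ["MK", "MT"]


def test_non_tcga_sequence_rejected(tmp_path):
    path = tmp_path / "amb.fna"
    path.write_text(">amb\nACGTN\n")
    with pytest.raises(SequenceAlphabetError):
        read_genome(str(path), fmt="fasta")


def test_fasta_gff_minus_strand_translation(tmp_path):
    """A minus-strand CDS at 1-based 4..12 maps to [3, 12) and translates
    from the reverse complement of the 9-mer."""
    rev_cds = "ATGAAATAA"  # M K stop
    fwd_segment = reverse_complement(rev_cds)
    seq = "ACG" + fwd_segment + "ACGT"
    (tmp_path / "g.fna").write_text(f">g\n{seq}\n")
    (tmp_path / "g.gff").write_text(
        "##gff-version 3\n"
        "g\ttest\tCDS\t4\t12\t.\t-\t0\tID=gene1\n"
    )
    g = read_genome(str(tmp_path / "g.fna"), fmt="fasta+gff",
                    gff_path=str(tmp_path / "g.gff"))
    (gene,) = g.genes
    assert (gene.start, gene.end, gene.strand) == (3, 12, "-")
    assert gene.translation == "MK"


def test_genbank_cds_without_derivable_translation(tmp_path):
    text = GENBANK_TWO_CDS.replace('                     /translation="MK"\n', "")
    # gp1 spans 5..13: ATGAAATAA -> derivable; break it by pointing at a
    # non-multiple-of-3 span instead.
    text = text.replace("CDS             5..13", "CDS             5..14")
    path = tmp_path / "bad.gbk"
    path.write_text(text)
    with pytest.raises(FeatureError):
        read_genome(str(path), fmt="genbank")


@pytest.mark.parametrize("writer,fmt", [(write_genbank, "genbank"), (None, "fasta+gff")])
def test_round_trip_preserves_genes(tmp_path, writer, fmt, small_dataset):
    """Write then read reproduces coordinates, strands, and translations."""
    genomes, _, _ = small_dataset
    g = genomes[0]
    if fmt == "genbank":
        path = tmp_path / "rt.gbk"
        writer(g, str(path))
        back = read_genome(str(path), fmt="genbank")
    else:
        fna, gff = tmp_path / "rt.fna", tmp_path / "rt.gff"
        write_fasta(g, str(fna))
        write_gff3(g, str(gff))
        back = read_genome(str(fna), fmt="fasta+gff", gff_path=str(gff))
    assert back.sequence == g.sequence
    assert len(back.genes) == len(g.genes)
    for orig, rt in zip(g.genes, back.genes):
        assert (rt.start, rt.end, rt.strand) == (orig.start, orig.end, orig.strand)
        assert rt.translation == orig.translation


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def _brute_force_orfs(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Independent enumeration: for every in-frame stop, the ORF from the
    earliest start codon after the previous stop."""
    starts, stops = {"ATG", "GTG", "TTG"}, {"TAA", "TAG", "TGA"}
    L = len(seq)
    out = set()
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            codon_pos = list(range(frame, L - 2, 3))
            codons = [s[i:i + 3] for i in codon_pos]
            stop_idx = [k for k, c in enumerate(codons) if c in stops]
            prev = -1
            for k in stop_idx:
                cand = [m for m in range(prev + 1, k) if codons[m] in starts]
                if cand and (k - cand[0]) >= min_aa:
                    lo, hi = codon_pos[cand[0]], codon_pos[k] + 3
                    if strand == "+":
                        out.add((lo, hi, "+"))
                    else:
                        out.add((L - hi, L - lo, "-"))
                prev = k
    return out


def test_single_constructed_orf():
    rng = np.random.default_rng(3)
    sense = [c for c in ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
             if c not in {"TAA", "TAG", "TGA", "ATG", "GTG", "TTG"}]
    body = "".join(rng.choice(sense, size=32))
    seq = "CCCCC" + "ATG" + body + "TAA" + "CCCCC"
    g = call_orfs(GenomeRecord("t", seq), min_aa=30)
    genes = [x for x in g.genes if x.strand == "+"]
    assert len(genes) == 1
    assert genes[0].length_aa == 33  # start codon + 32 sense codons
    assert genes[0].translation.startswith("M")


def test_no_stop_codons_no_orfs():
    g = call_orfs(GenomeRecord("a", "A" * 300), min_aa=30)
    assert g.genes == []


def test_call_orfs_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 50_000)
    called = call_orfs(GenomeRecord("r", seq), min_aa=30)
    got = {(g.start, g.end, g.strand) for g in called.genes}
    assert got == _brute_force_orfs(seq, 30)
    # translation length invariant for ORF-called genes
    for g in called.genes:
        assert (g.end - g.start) % 3 == 0
        assert g.length_aa == (g.end - g.start) // 3 - 1


def test_min_aa_floor_enforced():
    with pytest.raises(ValueError):
        call_orfs(GenomeRecord("a", "ATGAAATAA"), min_aa=5)


# ---------------------------------------------------------------------------
# Circular reorientation
# ---------------------------------------------------------------------------

def _toy_circular():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 100)
    genes = [
        GeneRecord("g1", "circ", 10, 22, "+", "MAAA"),
        GeneRecord("g2", "circ", 40, 52, "+", "MCCC"),
        GeneRecord("g3", "circ", 70, 82, "-", "MDDD"),
    ]
    return GenomeRecord("circ", seq, circular=True, genes=genes)


def test_reorient_rotation_identity():
    g = _toy_circular()
    out = reorient_circular(g, "g2")
    anchor = [x for x in out.genes if x.gene_id == "g2"][0]
    assert anchor.start == 0
    assert out.sequence == g.sequence[40:] + g.sequence[:40]


def test_reorient_anchor_already_at_zero():
    g = _toy_circular()
    g.genes[0].start, g.genes[0].end = 0, 12
    out = reorient_circular(g, "g1")
    assert out.sequence == g.sequence
    assert [(x.start, x.end) for x in out.genes] == [(x.start, x.end) for x in g.genes]


def test_reorient_preserves_intergene_distances_mod_length():
    g = _toy_circular()
    L = len(g.sequence)
    before = {(a.gene_id, b.gene_id): (b.start - a.start) % L
              for a in g.genes for b in g.genes}
    out = reorient_circular(g, "g2")
    after = {(a.gene_id, b.gene_id): (b.start - a.start) % L
             for a in out.genes for b in out.genes}
    assert before == after


def test_reorient_twice_returns_original_rotation():
    g = _toy_circular()
    once = reorient_circular(g, "g2")
    # anchoring back on the gene that now sits where the rotation started
    back = [x for x in once.genes if x.start == (10 - 40) % 100][0]
    twice = reorient_circular(once, back.gene_id)
    anchored_direct = reorient_circular(g, "g1")
    assert twice.sequence == anchored_direct.sequence


def test_reorient_errors():
    g = _toy_circular()
    with pytest.raises(ValueError):
        reorient_circular(g, "g3")  # minus-strand anchor undefined
    g2 = _toy_circular()
    g2.circular = False
    with pytest.raises(ValueError):
        reorient_circular(g2, "g1")
    with pytest.raises(ValueError):
        reorient_circular(_toy_circular(), "nope")
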