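"""Genome I/O, de novo ORF calling, and circular-origin normalization.

Reads annotated phage genomes from GenBank flat files, paired FASTA+GFF3,
or bare FASTA (genes then called de novo with :func:`call_orfs`). All
coordinates are converted to 0-based half-open at this boundary and back
again on write. Sequences containing characters outside {A, C, G, T} are
rejected outright — ambiguity codes are not masked, they disqualify the
genome.

tRNA/tmRNA features are parsed and retained as genome metadata but are
excluded from the gene list: every downstream similarity metric is defined
on protein-coding genes only.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .records import GeneRecord, GenomeRecord, VALID_NUCLEOTIDES

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
TRANSLATION_TABLE = 11

RNA_FEATURE_TYPES = frozenset({"tRNA", "tmRNA"})


class FormatError(ValueError):
    """The file does not parse under the named standard."""


class SequenceAlphabetError(ValueError):
    """The nucleotide sequence contains characters outside {A, C, G, T}."""


class FeatureError(ValueError):
    """A feature is malformed or its translation cannot be derived."""


def _check_alphabet(genome_id: str, sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - VALID_NUCLEOTIDES
    if bad:
        raise SequenceAlphabetError(
            f"genome {genome_id}: sequence contains non-TCGA characters "
            f"{sorted(bad)}; such sequences are rejected"
        )
    return sequence


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(nt: str, gene_id: str = "?") -> str:
    """Translate a CDS nucleotide sequence (table 11, stop trimmed).

    Alternative start codons (GTG/TTG) are rendered as M, per convention.
    """
    if len(nt) % 3 != 0:
        raise FeatureError(f"gene {gene_id}: CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise FeatureError(f"gene {gene_id}: internal stop codon in CDS")
    if not aa:
        raise FeatureError(f"gene {gene_id}: zero-length translation")
    if nt[:3] in START_CODONS:
        aa = "M" + aa[1:]
    return aa


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome(
    path: str,
    fmt: str = "genbank",
    gff_path: Optional[str] = None,
    genome_id: Optional[str] = None,
) -> GenomeRecord:
    """Read one genome from ``path`` in the named format.

    fmt="genbank": CDS features become genes; a /translation qualifier is
    used when present, otherwise the translation is derived with table 11.
    fmt="fasta+gff": gene coordinates come from ``gff_path`` (GFF3, 1-based
    inclusive) and translations are derived from the sequence.
    fmt="fasta": the bare sequence; call :func:`call_orfs` afterwards.
    """
    if fmt == "genbank":
        return _read_genbank(path, genome_id)
    if fmt == "fasta+gff":
        if gff_path is None:
            raise ValueError("fmt='fasta+gff' requires gff_path")
        return _read_fasta_gff(path, gff_path, genome_id)
    if fmt == "fasta":
        return _read_fasta(path, genome_id)
    raise ValueError(f"unknown format {fmt!r}; expected genbank, fasta+gff, or fasta")


def _read_fasta(path: str, genome_id: Optional[str]) -> GenomeRecord:
    try:
        rec = next(SeqIO.parse(path, "fasta"))
    except StopIteration:
        raise FormatError(f"{path}: no FASTA record found") from None
    gid = genome_id or rec.id
    seq = _check_alphabet(gid, str(rec.seq))
    return GenomeRecord(genome_id=gid, sequence=seq)


def _read_genbank(path: str, genome_id: Optional[str]) -> GenomeRecord:
    try:
        rec = SeqIO.read(path, "genbank")
    except Exception as exc:  # biopython raises bare ValueError on parse failure
        raise FormatError(f"{path}: GenBank parse failure: {exc}") from exc
    gid = genome_id or rec.name or rec.id
    seq = _check_alphabet(gid, str(rec.seq))
    circular = rec.annotations.get("topology", "linear") == "circular"

    genes: list[GeneRecord] = []
    rna_notes: list[str] = []
    n = 0
    for feat in rec.features:
        if feat.type in RNA_FEATURE_TYPES:
            rna_notes.append(
                f"{feat.type}:{int(feat.location.start)}..{int(feat.location.end)}"
                f"({'+' if feat.location.strand != -1 else '-'})"
            )
            continue
        if feat.type != "CDS":
            continue
        n += 1
        if len(feat.location.parts) != 1:
            raise FeatureError(
                f"{path}: CDS feature #{n} has a compound (join) location; not supported"
            )
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        quals = feat.qualifiers
        gene_id = (
            quals.get("locus_tag", [None])[0]
            or quals.get("gene", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"{gid}_CDS_{n}"
        )
        translation = quals.get("translation", [None])[0]
        if translation is None:
            cds_nt = seq[start:end]
            if strand == "-":
                cds_nt = reverse_complement(cds_nt)
            try:
                translation = translate_cds(cds_nt, gene_id)
            except FeatureError as exc:
                raise FeatureError(
                    f"{path}: CDS {gene_id}: no /translation and none derivable: {exc}"
                ) from exc
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=gid,
                start=start,
                end=end,
                strand=strand,
                translation=translation,
                name=quals.get("gene", [None])[0] or gene_id,
                function=quals.get("product", [None])[0],
            )
        )
    metadata = {"source": "genbank", "accession": rec.id}
    if rna_notes:
        metadata["rna_features"] = ";".join(rna_notes)
    return GenomeRecord(gid, seq, circular=circular, genes=genes, metadata=metadata)


def _read_fasta_gff(path: str, gff_path: str, genome_id: Optional[str]) -> GenomeRecord:
    base = _read_fasta(path, genome_id)
    try:
        db = gffutils.create_db(
            gff_path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"{gff_path}: GFF3 parse failure: {exc}") from exc

    genes: list[GeneRecord] = []
    rna_notes: list[str] = []
    n = 0
    for feat in db.all_features(order_by=("start", "end")):
        if feat.featuretype in RNA_FEATURE_TYPES:
            rna_notes.append(f"{feat.featuretype}:{feat.start - 1}..{feat.end}({feat.strand})")
            continue
        if feat.featuretype != "CDS":
            continue
        n += 1
        start = feat.start - 1  # GFF3 is 1-based inclusive
        end = feat.end
        if not (0 <= start < end <= len(base.sequence)):
            raise FeatureError(
                f"{gff_path}: CDS {feat.id or n} interval {feat.start}..{feat.end} "
                f"outside genome of length {len(base.sequence)}"
            )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        gene_id = feat.id or feat.attributes.get("Name", [None])[0] or f"{base.genome_id}_CDS_{n}"
        cds_nt = base.sequence[start:end]
        if strand == "-":
            cds_nt = reverse_complement(cds_nt)
        translation = translate_cds(cds_nt, gene_id)
        product = feat.attributes.get("product", [None])[0]
        pham = feat.attributes.get("pham_id", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=base.genome_id,
                start=start,
                end=end,
                strand=strand,
                translation=translation,
                pham_id=pham,
                name=feat.attributes.get("Name", [None])[0] or gene_id,
                function=product,
            )
        )
    base.genes = genes
    base.__post_init__()  # re-sort and re-validate
    if rna_notes:
        base.metadata["rna_features"] = ";".join(rna_notes)
    base.metadata["source"] = "fasta+gff"
    return base


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(genome: GenomeRecord, path: str) -> None:
    """Write the genome sequence as FASTA with 70-column wrapping."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file([rec])


def write_gff3(genome: GenomeRecord, path: str) -> None:
    """Write gene calls as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome.sequence)}\n")
        for g in genome.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.name and g.name != g.gene_id:
                attrs.append(f"Name={g.name}")
            if g.function:
                attrs.append(f"product={g.function}")
            if g.pham_id:
                attrs.append(f"pham_id={g.pham_id}")
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "phamkit",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_genbank(genome: GenomeRecord, path: str) -> None:
    """Write a GenBank flat file with CDS features carrying translations."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description=genome.metadata.get("description", ""),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for g in genome.genes:
        quals = {
            "locus_tag": [g.gene_id],
            "translation": [g.translation],
            "transl_table": [str(TRANSLATION_TABLE)],
        }
        if g.name:
            quals["gene"] = [g.name]
        if g.function:
            quals["product"] = [g.function]
        rec.features.append(
            SeqFeature(
                FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    SeqIO.write([rec], path, "genbank")


def write_gene_table(genomes: Iterable[GenomeRecord], path: str) -> pd.DataFrame:
    """Write the dataset-wide TSV gene table and return it as a DataFrame."""
    rows = [
        {
            "genome_id": gm.genome_id,
            "gene_id": g.gene_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "pham_id": g.pham_id if g.pham_id is not None else "",
        }
        for gm in genomes
        for g in gm.genes
    ]
    df = pd.DataFrame(rows, columns=["genome_id", "gene_id", "start", "end", "strand", "pham_id"])
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def call_orfs(genome: GenomeRecord, min_aa: int = 30) -> GenomeRecord:
    """De novo gene calling: maximal ORFs in all six reading frames.

    Starts are ATG/GTG/TTG, stops TAA/TAG/TGA (translation table 11).
    Nested ORFs sharing a stop codon are resolved by keeping the longest
    (the earliest start after the previous in-frame stop). Only ORFs
    closed by a stop codon count, and the stop is excluded from the
    translation, so an ORF of ``k`` codons plus stop yields ``k`` amino
    acids. Deliberately simple and deterministic — a transparent stand-in
    for production gene callers, not a competitor to them.
    """
    if not genome.sequence:
        raise ValueError("genome sequence is empty")
    if min_aa < 10:
        raise ValueError(f"min_aa must be >= 10, got {min_aa}")

    L = len(genome.sequence)
    found: list[tuple[int, int, str, str]] = []  # (start, end, strand, translation)
    for strand, seq in (("+", genome.sequence), ("-", reverse_complement(genome.sequence))):
        for frame in range(3):
            first_start: Optional[int] = None
            for i in range(frame, L - 2, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    if first_start is not None:
                        aa_len = (i - first_start) // 3
                        if aa_len >= min_aa:
                            orf_nt = seq[first_start : i + 3]
                            translation = translate_cds(orf_nt)
                            if strand == "+":
                                found.append((first_start, i + 3, "+", translation))
                            else:
                                found.append((L - (i + 3), L - first_start, "-", translation))
                    first_start = None
                elif first_start is None and codon in START_CODONS:
                    first_start = i

    found.sort(key=lambda t: (t[0], t[1], t[2]))
    out = genome.copy()
    out.genes = [
        GeneRecord(
            gene_id=f"gene_{k + 1}",
            genome_id=genome.genome_id,
            start=s,
            end=e,
            strand=st,
            translation=aa,
            name=str(k + 1),
        )
        for k, (s, e, st, aa) in enumerate(found)
    ]
    out.__post_init__()
    return out


# ---------------------------------------------------------------------------
# Circular reorientation
# ---------------------------------------------------------------------------

def reorient_circular(genome: GenomeRecord, anchor_gene_id: str) -> GenomeRecord:
    """Rotate a circular genome so the anchor gene starts at coordinate 0.

    The convention places coordinate 1 at the first base of the terminase
    gene (or a nearby gene after a non-coding gap). Reorientation to a
    reverse-strand anchor is undefined here and raises.
    """
    if not genome.circular:
        raise ValueError(f"genome {genome.genome_id} is not circular; cannot reorient")
    anchors = [g for g in genome.genes if g.gene_id == anchor_gene_id]
    if not anchors:
        raise ValueError(f"anchor gene {anchor_gene_id!r} not found in {genome.genome_id}")
    anchor = anchors[0]
    if anchor.strand != "+":
        raise ValueError(
            f"anchor gene {anchor_gene_id!r} is on the - strand; reorientation to a "
            "reverse gene start is undefined"
        )
    L = len(genome.sequence)
    shift = anchor.start
    out = genome.copy()
    out.sequence = genome.sequence[shift:] + genome.sequence[:shift]
    for g in out.genes:
        new_start = (g.start - shift) % L
        new_end = new_start + (g.end - g.start)
        if new_end > L:
            raise ValueError(
                f"gene {g.gene_id} would span the new origin after rotation; "
                "choose an anchor outside any gene interval"
            )
        g.start, g.end = new_start, new_end
    out.__post_init__()
    return out
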