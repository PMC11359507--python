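"""Core domain types for comparative phage genomics.

Coordinates are 0-based half-open on the forward strand throughout the
package; conversion from the 1-based inclusive conventions of GenBank and
GFF3 happens only at the I/O boundary (:mod:`phamkit.seqio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

VALID_NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_AMINO_ACIDS = frozenset(AMINO_ACIDS + "X")


@dataclass
class GeneRecord:
    """One predicted protein-coding gene.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    parent genome; ``translation`` is the amino-acid sequence without the
    stop. ``pham_id`` is assigned by pham assembly and is ``None`` until
    then. ``name`` and ``function`` feed the genome-map renderer.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    translation: str
    pham_id: Optional[str] = None
    name: Optional[str] = None
    function: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not self.translation:
            raise ValueError(f"gene {self.gene_id}: empty translation")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return len(self.translation)

    @property
    def key(self) -> tuple[str, str]:
        """Dataset-wide unique key (genome_id, gene_id)."""
        return (self.genome_id, self.gene_id)


@dataclass
class GenomeRecord:
    """A phage genome: nucleotide sequence plus its ordered gene calls.

    ``sequence`` is uppercase over {A, C, G, T}; ambiguity characters are
    rejected at read time rather than masked. ``genes`` are kept sorted by
    start coordinate. ``metadata`` holds free-form string annotations
    (host, cluster, accession, retained tRNA/tmRNA coordinates, ...).
    """

    genome_id: str
    sequence: str
    circular: bool = False
    genes: list[GeneRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"genome {self.genome_id}: sequence contains non-TCGA characters "
                f"{sorted(bad)}; ambiguous or invalid sequences are rejected"
            )
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} interval [{g.start}, {g.end}) exceeds "
                    f"genome length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "GenomeRecord":
        return GenomeRecord(
            genome_id=self.genome_id,
            sequence=self.sequence,
            circular=self.circular,
            genes=[replace(g) for g in self.genes],
            metadata=dict(self.metadata),
        )


@dataclass
class Pham:
    """A phamily: the set of genes judged homologous across a dataset.

    Members are (genome_id, gene_id) keys. A pham with a single member is
    an *orpham*. The representative is the member with the longest
    translation (ties broken by key order).
    """

    pham_id: str
    members: frozenset[tuple[str, str]]
    representative: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pham {self.pham_id}: empty member set")
        if self.representative not in self.members:
            raise ValueError(f"pham {self.pham_id}: representative not a member")

    @property
    def is_orpham(self) -> bool:
        return len(self.members) == 1

    def __len__(self) -> int:
        return len(self.members)


def pham_lookup(phams: list[Pham]) -> dict[tuple[str, str], str]:
    """Map every (genome_id, gene_id) key to its pham_id."""
    table: dict[tuple[str, str], str] = {}
    for p in phams:
        for m in p.members:
            if m in table:
                raise ValueError(f"gene {m} assigned to two phams")
            table[m] = p.pham_id
    return table


def apply_pham_labels(genomes: list[GenomeRecord], phams: list[Pham]) -> None:
    """Write pham_id labels onto the gene records in place."""
    table = pham_lookup(phams)
    for genome in genomes:
        for gene in genome.genes:
            if gene.key in table:
                gene.pham_id = table[gene.key]
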