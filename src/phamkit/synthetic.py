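"""Synthetic mosaic phage genome datasets with planted ground truth.

Emulates the mosaic structure of dsDNA phage genomes: clusters of genomes
share a core repertoire of gene phamilies, accessory phamilies are drawn
per genome from a cluster pool, horizontally transferred genes arrive
from a global foreign pool, and proteins diverge from their phamily
ancestor by iid amino-acid substitutions. Nucleotide sequences are
back-translated once per ancestral phamily (uniform synonymous codon
choice), genomes inherit those codons, amino-acid substitutions re-draw
the affected codon, and additional nucleotide divergence is applied as
synonymous-only substitutions so every gene's translation always equals
the translation of its CDS. Gene CDSs are laid head-to-tail with
fixed-length random intergenic spacers; each phamily's spacer and strand
are drawn once by a seeded coin and travel with the phamily, so genomes
with identical repertoires and zero divergence are byte-identical.

All randomness flows from one integer seed through numpy's default
PCG64 generator, so an identical spec and seed reproduce the dataset
byte for byte on any platform. With every divergence rate at zero and no
HGT, all genomes of a cluster are identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np
from Bio.Data import CodonTable

from .records import AMINO_ACIDS, GeneRecord, GenomeRecord

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOPS = tuple(sorted(_TABLE11.stop_codons))
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(aa, ())
    AA_TO_CODONS[aa] = AA_TO_CODONS[aa] + (codon,)

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Divergence rates are per-site substitution probabilities per lineage:
    each genome's proteins diverge from their (sub)cluster ancestor at
    ``aa_divergence``; with ``n_subclusters`` > 1 each subcluster ancestor
    first diverges from the cluster ancestor at ``subcluster_divergence``.
    ``nt_divergence`` adds synonymous-only nucleotide substitutions on top.
    ``hgt_rate`` is the expected number of foreign-pool gene insertions
    per genome (Poisson). Gene lengths (amino acids) are normal with the
    stated mean/sd, truncated below at ``gene_length_min``.
    """

    seed: int = 0
    n_clusters: int = 4
    genomes_per_cluster: int = 5
    n_subclusters: int = 1
    phams_per_genome: int = 30
    core_fraction: float = 0.8
    aa_divergence: float = 0.05
    subcluster_divergence: float = 0.25
    nt_divergence: float = 0.02
    hgt_rate: float = 1.0
    gene_length_mean: float = 200.0
    gene_length_sd: float = 40.0
    gene_length_min: int = 50
    intergenic_gap: int = 50

    def validate(self) -> None:
        bad = []
        for name in ("core_fraction", "aa_divergence", "subcluster_divergence", "nt_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name}={v} (must lie in [0, 1])")
        for name in ("n_clusters", "genomes_per_cluster", "n_subclusters",
                     "phams_per_genome", "gene_length_min", "intergenic_gap"):
            v = getattr(self, name)
            if v <= 0 and name != "intergenic_gap" or v < 0:
                bad.append(f"{name}={v} (must be positive)")
        if self.hgt_rate < 0:
            bad.append(f"hgt_rate={self.hgt_rate} (must be >= 0)")
        if self.gene_length_mean < self.gene_length_min:
            bad.append("gene_length_mean below gene_length_min")
        if bad:
            raise ValueError("invalid simulation spec: " + "; ".join(bad))

    def to_flat(self) -> str:
        """Flat key=value serialization (one per line)."""
        return "".join(f"{k}={v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_flat(cls, text: str) -> "SimulationSpec":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown simulation spec key {key!r}")
            target = cls.__dataclass_fields__[key].type
            kwargs[key] = float(value) if "float" in str(target) else int(value)
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Planted labels for one simulated dataset."""

    cluster_of: dict[str, str]
    subcluster_of: dict[str, Optional[str]]
    source_pham: dict[tuple[str, str], str]
    spec: SimulationSpec = field(default_factory=SimulationSpec)


RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mutate_sequence(seq: str, rate: float, alphabet: str, seed: RngLike) -> str:
    """iid per-site substitution to a uniformly chosen *different* symbol.

    Length-preserving and reproducible under a fixed seed. rate=0 is the
    identity; rate=1 changes every position.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if rate == 0.0 or not seq:
        return seq
    rng = _rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    alpha = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        # choose among the k-1 symbols differing from the current one
        current_idx = np.searchsorted(np.sort(alpha), arr[hits])
        order = np.argsort(alpha, kind="stable")
        sorted_alpha = alpha[order]
        pick = rng.integers(0, len(alpha) - 1, size=len(hits))
        pick = np.where(pick >= current_idx, pick + 1, pick)
        arr[hits] = sorted_alpha[pick]
    return arr.tobytes().decode("ascii")


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


def _back_translate(protein: str, rng: np.random.Generator) -> list[str]:
    """One codon per residue, uniform among synonymous codons; plus a stop."""
    codons = [
        AA_TO_CODONS[aa][rng.integers(0, len(AA_TO_CODONS[aa]))] for aa in protein
    ]
    codons.append(STOPS[rng.integers(0, len(STOPS))])
    return codons


def _diverge_codons(
    codons: list[str], aa_rate: float, nt_rate: float, rng: np.random.Generator
) -> tuple[list[str], str]:
    """Apply amino-acid then synonymous nucleotide divergence to a gene.

    Amino-acid substitutions re-draw the affected codon uniformly among
    the new residue's codons; nucleotide substitutions are accepted only
    when synonymous, so translation always matches the CDS. The stop
    codon is left untouched. Returns (codons, protein).
    """
    out = list(codons)
    ncod = len(out) - 1  # excluding stop
    if aa_rate > 0:
        hits = np.nonzero(rng.random(ncod) < aa_rate)[0]
        for i in hits:
            old_aa = CODON_TO_AA[out[i]]
            choices = [a for a in AMINO_ACIDS if a != old_aa]
            new_aa = choices[rng.integers(0, len(choices))]
            out[i] = AA_TO_CODONS[new_aa][rng.integers(0, len(AA_TO_CODONS[new_aa]))]
    if nt_rate > 0:
        for i in range(ncod):
            codon = out[i]
            changed = False
            clist = list(codon)
            for p in range(3):
                if rng.random() < nt_rate:
                    alts = [b for b in NUCLEOTIDES if b != clist[p]]
                    cand = alts[rng.integers(0, 3)]
                    trial = clist.copy()
                    trial[p] = cand
                    if CODON_TO_AA.get("".join(trial)) == CODON_TO_AA[codon]:
                        clist = trial
                        changed = True
            if changed:
                out[i] = "".join(clist)
    protein = "".join(CODON_TO_AA[c] for c in out[:-1])
    return out, protein


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expected_pairwise_identity(rate: float) -> float:
    """Expected per-site identity of two sequences independently diverged
    from a common ancestor at per-site rate ``rate`` over a 20-letter
    alphabet: (1-d)^2 + d^2/19."""
    return (1.0 - rate) ** 2 + rate**2 / 19.0


def simulate_dataset(spec: SimulationSpec) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate a mosaic genome dataset with planted labels.

    Clusters draw from disjoint pham pools; genomes within a cluster
    share the core fraction of the repertoire and sample the rest from
    the cluster's accessory pool; HGT genes come from a global foreign
    pool. Returns the genomes (valid, writer-ready records) and the
    planted truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def draw_length() -> int:
        return max(spec.gene_length_min, int(round(rng.normal(spec.gene_length_mean, spec.gene_length_sd))))

    n_core = int(round(spec.core_fraction * spec.phams_per_genome))
    n_accessory_per_genome = spec.phams_per_genome - n_core
    accessory_pool_size = max(n_accessory_per_genome, spec.phams_per_genome)

    total_genomes = spec.n_clusters * spec.genomes_per_cluster
    foreign_pool_size = max(1, int(np.ceil(spec.hgt_rate * total_genomes * 2)))
    foreign_pool = {
        f"hgt_p{k + 1}": _back_translate(_random_protein(draw_length(), rng), rng)
        for k in range(foreign_pool_size)
    }
    foreign_ids = sorted(foreign_pool)
    # Spacer sequence and strand travel with the pham, so genomes sharing a
    # repertoire are byte-identical when every divergence rate is zero.
    spacer_of = {
        pid: "".join(rng.choice(list(NUCLEOTIDES), size=spec.intergenic_gap))
        for pid in foreign_ids
    }
    strand_of = {pid: ("+" if rng.random() < 0.5 else "-") for pid in foreign_ids}

    genomes: list[GenomeRecord] = []
    cluster_of: dict[str, str] = {}
    subcluster_of: dict[str, Optional[str]] = {}
    source_pham: dict[tuple[str, str], str] = {}

    for ci in range(1, spec.n_clusters + 1):
        cluster_label = f"cluster_{ci}"
        pham_ids = [f"c{ci}_p{k + 1}" for k in range(n_core + accessory_pool_size)]
        ancestors = {pid: _back_translate(_random_protein(draw_length(), rng), rng) for pid in pham_ids}
        core_ids = pham_ids[:n_core]
        accessory_ids = pham_ids[n_core:]
        for pid in pham_ids:
            spacer_of[pid] = "".join(rng.choice(list(NUCLEOTIDES), size=spec.intergenic_gap))
            strand_of[pid] = "+" if rng.random() < 0.5 else "-"
        tail_spacer = "".join(rng.choice(list(NUCLEOTIDES), size=spec.intergenic_gap))

        # genome -> subcluster assignment, round-robin for balance
        sub_assign = [(g % spec.n_subclusters) + 1 for g in range(spec.genomes_per_cluster)]

        sub_ancestors: dict[int, dict[str, list[str]]] = {}
        for si in range(1, spec.n_subclusters + 1):
            if spec.n_subclusters == 1:
                sub_ancestors[si] = ancestors
            else:
                sub_ancestors[si] = {
                    pid: _diverge_codons(cod, spec.subcluster_divergence, 0.0, rng)[0]
                    for pid, cod in ancestors.items()
                }

        for gi in range(1, spec.genomes_per_cluster + 1):
            si = sub_assign[gi - 1]
            genome_id = f"c{ci:02d}s{si}g{gi:02d}"
            base = sub_ancestors[si]
            chosen_accessory = sorted(
                rng.choice(accessory_ids, size=n_accessory_per_genome, replace=False)
            ) if n_accessory_per_genome else []
            n_hgt = int(rng.poisson(spec.hgt_rate))
            hgt_ids = sorted(
                rng.choice(foreign_ids, size=min(n_hgt, len(foreign_ids)), replace=False)
            ) if n_hgt else []

            gene_plan = [(pid, base[pid]) for pid in core_ids + chosen_accessory]
            gene_plan += [(fid, foreign_pool[fid]) for fid in hgt_ids]

            seq_parts: list[str] = []
            genes: list[GeneRecord] = []
            pos = 0
            for idx, (pid, anc_codons) in enumerate(gene_plan, start=1):
                spacer = spacer_of[pid]
                seq_parts.append(spacer)
                pos += len(spacer)
                codons, protein = _diverge_codons(
                    anc_codons, spec.aa_divergence, spec.nt_divergence, rng
                )
                cds = "".join(codons)
                strand = strand_of[pid]
                seq_parts.append(cds if strand == "+" else _revcomp(cds))
                gene_id = f"g{idx}"
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        genome_id=genome_id,
                        start=pos,
                        end=pos + len(cds),
                        strand=strand,
                        translation=protein,
                        name=str(idx),
                    )
                )
                source_pham[(genome_id, gene_id)] = pid
                pos += len(cds)
            seq_parts.append(tail_spacer)
            sub_label = f"{cluster_label}.{si}" if spec.n_subclusters > 1 else None
            genomes.append(
                GenomeRecord(
                    genome_id=genome_id,
                    sequence="".join(seq_parts),
                    circular=False,
                    genes=genes,
                    metadata={
                        "cluster": cluster_label,
                        **({"subcluster": sub_label} if sub_label else {}),
                    },
                )
            )
            cluster_of[genome_id] = cluster_label
            subcluster_of[genome_id] = sub_label

    truth = SyntheticTruth(
        cluster_of=cluster_of,
        subcluster_of=subcluster_of,
        source_pham=source_pham,
        spec=spec,
    )
    return genomes, truth
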