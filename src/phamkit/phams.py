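"""Pham assembly: assorting predicted proteins into phamilies.

Proteins are grouped by thresholded pairwise global-alignment similarity
with single-linkage closure: candidate pairs survive a k-mer Jaccard
prefilter, are verified by alignment (identity and coverage thresholds),
and phams are the connected components of the verified-edge graph. A pham
with one member is an orpham. Pham semantics are transitive ("genes that
are related to one another"), hence single linkage rather than centroid
clustering.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .records import GeneRecord, Pham, VALID_AMINO_ACIDS

DEFAULT_MIN_IDENTITY = 0.35
DEFAULT_MIN_COVERAGE = 0.80
# Prefilter defaults are deliberately permissive: a pair at the 35% identity
# floor shares ~0.35^4 of its 4-mers (Jaccard ~0.01), comfortably above the
# 0.005 gate, while unrelated pairs sit near 0.0006 and are skipped.
DEFAULT_KMER_SIZE = 4
DEFAULT_MIN_KMER_JACCARD = 0.005

_aligner: Optional[Align.PairwiseAligner] = None


def _get_aligner() -> Align.PairwiseAligner:
    # BLOSUM62 with BLASTP-style affine gaps; built once, reused.
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def _validate_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(seq) - VALID_AMINO_ACIDS
    if bad:
        raise ValueError(f"{label}: invalid amino-acid characters {sorted(bad)}")


def protein_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity and coverage of two protein sequences.

    Identity is the fraction of identical aligned positions over alignment
    columns excluding terminal gaps; an X never counts as a match, even
    against another X. Coverage is the aligned span of the shorter
    sequence divided by its length. Symmetric: f(a, b) == f(b, a),
    enforced by aligning the arguments in canonical order.
    """
    _validate_protein(a, "a")
    _validate_protein(b, "b")
    # Canonical argument order guarantees symmetry even when the optimal
    # alignment is degenerate.
    if (len(b), b) < (len(a), a):
        a, b = b, a
    if a == b and "X" not in a:
        return 1.0, 1.0

    aln = _get_aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ncol = len(s1)

    # Strip terminal gap columns (gap runs at either end of either row).
    lo = 0
    while lo < ncol and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    hi = ncol
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    core_cols = hi - lo
    if core_cols == 0:
        return 0.0, 0.0

    ident = sum(
        1
        for i in range(lo, hi)
        if s1[i] == s2[i] and s1[i] != "-" and s1[i] != "X"
    )
    identity = ident / core_cols

    shorter = a if len(a) <= len(b) else b
    shorter_row = s1 if shorter is a else s2
    span = sum(1 for i in range(lo, hi) if shorter_row[i] != "-")
    coverage = span / len(shorter)
    return identity, coverage


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _candidate_pairs(
    keys: Sequence[tuple[str, str]],
    kmer_sets: dict[tuple[str, str], frozenset[str]],
    min_jaccard: float,
) -> Iterable[tuple[tuple[str, str], tuple[str, str]]]:
    """Pairs whose k-mer Jaccard meets the threshold, via an inverted index."""
    if min_jaccard <= 0.0:
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                yield ka, kb
        return
    index: dict[str, list[int]] = defaultdict(list)
    for idx, key in enumerate(keys):
        for kmer in kmer_sets[key]:
            index[kmer].append(idx)
    shared: Counter[tuple[int, int]] = Counter()
    for members in index.values():
        if len(members) < 2:
            continue
        for i, ia in enumerate(members):
            for ib in members[i + 1 :]:
                shared[(ia, ib)] += 1
    for (ia, ib), inter in shared.items():
        ka, kb = keys[ia], keys[ib]
        union = len(kmer_sets[ka]) + len(kmer_sets[kb]) - inter
        if inter / union >= min_jaccard:
            yield ka, kb


def build_phams(
    genes: Sequence[GeneRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    kmer_size: int = DEFAULT_KMER_SIZE,
    min_kmer_jaccard: float = DEFAULT_MIN_KMER_JACCARD,
) -> list[Pham]:
    """Assort all genes in a dataset into phams.

    Candidate pairs are those whose translation k-mer Jaccard reaches
    ``min_kmer_jaccard`` (0 disables the prefilter: all pairs are
    candidates); verified edges are candidates meeting both the identity
    and coverage thresholds under :func:`protein_identity`; phams are the
    connected components of the verified-edge graph. Pham ids are assigned
    deterministically: components ordered by their lexicographically
    smallest (genome_id, gene_id) member key, numbered from 1. Every gene
    lands in exactly one pham; singletons are orphams.
    """
    if not genes:
        raise ValueError("no genes supplied")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("min_identity and min_coverage must lie in (0, 1]")

    by_key: dict[tuple[str, str], GeneRecord] = {}
    for g in genes:
        if g.key in by_key:
            raise ValueError(f"duplicate gene key {g.key}")
        _validate_protein(g.translation, f"gene {g.key}")
        by_key[g.key] = g
    keys = sorted(by_key)

    kmer_sets = {k: _kmer_set(by_key[k].translation, kmer_size) for k in keys}

    graph = nx.Graph()
    graph.add_nodes_from(keys)
    # Cache alignments by sequence pair: identical translations recur.
    seen: dict[tuple[str, str], tuple[float, float]] = {}
    for ka, kb in _candidate_pairs(keys, kmer_sets, min_kmer_jaccard):
        sa, sb = by_key[ka].translation, by_key[kb].translation
        pair = (sa, sb) if sa <= sb else (sb, sa)
        if pair not in seen:
            seen[pair] = protein_identity(sa, sb)
        identity, coverage = seen[pair]
        if identity >= min_identity and coverage >= min_coverage:
            graph.add_edge(ka, kb)

    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    phams: list[Pham] = []
    for num, comp in enumerate(components, start=1):
        members = frozenset(comp)
        # Representative: longest translation, ties to the smallest key.
        best_len = max(len(by_key[k].translation) for k in members)
        rep = min(k for k in members if len(by_key[k].translation) == best_len)
        phams.append(Pham(pham_id=str(num), members=members, representative=rep))
    return phams


def pham_table(phams: Sequence[Pham]) -> "pd.DataFrame":
    """Long-form pham table (pham_id, genome_id, gene_id), sorted."""
    import pandas as pd

    rows = [
        {"pham_id": p.pham_id, "genome_id": gid, "gene_id": gene}
        for p in phams
        for gid, gene in sorted(p.members)
    ]
    return pd.DataFrame(rows, columns=["pham_id", "genome_id", "gene_id"])


def write_pham_table(phams: Sequence[Pham], path: str) -> None:
    pham_table(phams).to_csv(path, sep="\t", index=False)


def write_representatives_fasta(
    phams: Sequence[Pham], genes: Sequence[GeneRecord], path: str
) -> None:
    """FASTA of one representative translation per pham."""
    by_key = {g.key: g for g in genes}
    with open(path, "w") as fh:
        for p in phams:
            rep = by_key[p.representative]
            fh.write(f">pham_{p.pham_id}|{rep.genome_id}|{rep.gene_id}\n")
            for i in range(0, len(rep.translation), 70):
                fh.write(rep.translation[i : i + 70] + "\n")
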