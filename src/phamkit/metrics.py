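"""Pairwise genome similarity metrics.

Protein-level metrics, all on a 0-100 scale:

* GCS (gene content similarity): the mean over both genomes of the
  fraction of genes whose pham occurs in the partner genome.
* AAI: length-weighted mean amino-acid identity over paired homologues in
  shared phams.
* PEQ (proteomic equivalence quotient): a single value combining
  shared-gene proportion with homologue identity — the length-weighted
  identity sum over paired homologues divided by the total amino-acid
  length of both proteomes, so every unshared gene drags the quotient
  down. 100 iff the proteomes are identical under the pairing; 0 iff no
  pham is shared.

Nucleotide-level metric:

* gNI (genome-wide nucleotide identity): identical bases summed over
  E-value-filtered seed-and-extend local alignment segments (HSPs) in
  both query/subject roles, normalized over both genome lengths. 0 means
  no segment passes the E-value filter.

The PEQ formula lives in :func:`peq` alone so it can be swapped easily if
a different normalization is ever preferred.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phams import protein_identity
from .records import GeneRecord, GenomeRecord, Pham, pham_lookup
from .seqio import reverse_complement

DEFAULT_WORD_SIZE = 11
DEFAULT_EVALUE_MAX = 1e-4
DEFAULT_XDROP = 20
MATCH_SCORE = 1
MISMATCH_SCORE = -2
# Karlin-Altschul parameters for the ungapped +1/-2 scoring convention.
KA_LAMBDA = 1.28
KA_K = 0.46
_MIN_EVALUE = 1e-300  # E-values underflow on long perfect hits; keep them positive


@dataclass
class Hsp:
    """A high-scoring segment pair from ungapped seed-and-extend search.

    Intervals are 0-based half-open on the forward strands of query and
    subject; ``strand`` is the subject strand ('-' means the query matched
    the subject's reverse complement).
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identities: int
    strand: str
    evalue: float
    score: int = 0

    def __post_init__(self) -> None:
        qlen, slen = self.q_end - self.q_start, self.s_end - self.s_start
        if qlen <= 0 or slen <= 0:
            raise ValueError("empty HSP interval")
        if self.identities > min(qlen, slen):
            raise ValueError("identities exceed interval length")
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity_fraction(self) -> float:
        return self.identities / self.length


@dataclass
class PairwiseSimilarity:
    """All similarity values for one genome pair (percent scale)."""

    genome_a: str
    genome_b: str
    gcs: float
    aai: float
    peq: float
    gni: float


class SimilarityMatrix:
    """Symmetric pairwise genome similarity for one metric, 0-100 scale."""

    def __init__(self, ids: Sequence[str], values: np.ndarray, metric: str = ""):
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids")
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(values, values.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 100.0):
            raise ValueError("diagonal must be 100")
        if values.min() < -1e-9 or values.max() > 100 + 1e-9:
            raise ValueError("values must lie in [0, 100]")
        self.ids = ids
        self.values = np.clip(values, 0.0, 100.0)
        self.metric = metric
        self._index = {g: i for i, g in enumerate(ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"genome_a": self.ids[i], "genome_b": self.ids[j],
             "value": round(float(self.values[i, j]), 2)}
            for i in range(len(self.ids))
            for j in range(i + 1, len(self.ids))
        ]
        return pd.DataFrame(rows, columns=["genome_a", "genome_b", "value"])

    def write_square_tsv(self, path: str) -> None:
        self.to_dataframe().round(2).to_csv(path, sep="\t", index_label="genome_id")

    def write_long_tsv(self, path: str) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.2f")

    @classmethod
    def read_square_tsv(cls, path: str, metric: str = "") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), metric=metric)


# ---------------------------------------------------------------------------
# Protein-level metrics
# ---------------------------------------------------------------------------

def _pham_ids(genome: GenomeRecord, table: Optional[dict]) -> list[str]:
    out = []
    for g in genome.genes:
        pid = table.get(g.key) if table is not None else g.pham_id
        if pid is not None:
            out.append(pid)
    if not out:
        raise ValueError(f"genome {genome.genome_id} has no pham-assigned genes")
    return out


def _resolve_table(phams) -> Optional[dict]:
    if phams is None:
        return None
    if isinstance(phams, dict):
        return phams
    return pham_lookup(list(phams))


def gcs(a: GenomeRecord, b: GenomeRecord, phams=None) -> float:
    """Gene content similarity: mean directed shared-pham gene fraction, x100."""
    table = _resolve_table(phams)
    pa, pb = _pham_ids(a, table), _pham_ids(b, table)
    set_a, set_b = set(pa), set(pb)
    s_a = sum(1 for p in pa if p in set_b)
    s_b = sum(1 for p in pb if p in set_a)
    return 100.0 * (s_a / len(pa) + s_b / len(pb)) / 2.0


def _paired_homologues(
    a: GenomeRecord, b: GenomeRecord, table: Optional[dict]
) -> list[tuple[GeneRecord, GeneRecord, float]]:
    """Best-identity greedy bipartite pairing of homologues per shared pham.

    Paralogs (multiple members of one pham in one genome) are paired
    greedily by descending identity, ties broken by gene_id order;
    leftover copies stay unpaired.
    """
    def by_pham(genome: GenomeRecord) -> dict[str, list[GeneRecord]]:
        d: dict[str, list[GeneRecord]] = defaultdict(list)
        for g in genome.genes:
            pid = table.get(g.key) if table is not None else g.pham_id
            if pid is not None:
                d[pid].append(g)
        return d

    phams_a, phams_b = by_pham(a), by_pham(b)
    pairs: list[tuple[GeneRecord, GeneRecord, float]] = []
    for pid in sorted(set(phams_a) & set(phams_b)):
        ga, gb = phams_a[pid], phams_b[pid]
        scored = sorted(
            (
                (-protein_identity(x.translation, y.translation)[0], x.gene_id, y.gene_id, x, y)
                for x in ga
                for y in gb
            ),
            key=lambda t: t[:3],
        )
        used_a: set[str] = set()
        used_b: set[str] = set()
        for neg_id, xa_id, yb_id, x, y in scored:
            if xa_id in used_a or yb_id in used_b:
                continue
            used_a.add(xa_id)
            used_b.add(yb_id)
            pairs.append((x, y, -neg_id))
    return pairs


def aai_shared(a: GenomeRecord, b: GenomeRecord, phams=None) -> tuple[float, int]:
    """Length-weighted AAI over paired homologues in shared phams.

    Returns (aai_percent, shared_weight) where shared_weight is the summed
    amino-acid length (both members) of all paired homologues. (0, 0) when
    no pham is shared.
    """
    table = _resolve_table(phams)
    _pham_ids(a, table), _pham_ids(b, table)  # precondition: both have assignments
    pairs = _paired_homologues(a, b, table)
    if not pairs:
        return 0.0, 0
    weights = [x.length_aa + y.length_aa for x, y, _ in pairs]
    total = sum(weights)
    aai = 100.0 * sum(w * ident for w, (_, _, ident) in zip(weights, pairs)) / total
    return aai, total


def peq(a: GenomeRecord, b: GenomeRecord, phams=None) -> float:
    """Proteomic equivalence quotient (percent).

    PEQ = 100 x sum over paired homologues of (len_pair x identity) /
    total amino-acid length of all genes of both genomes, with
    len_pair = len(member in a) + len(member in b). Unshared genes
    contribute identity 0, so PEQ is 100 iff the proteomes are identical
    under the pairing and 0 iff no pham is shared.
    """
    table = _resolve_table(phams)
    _pham_ids(a, table), _pham_ids(b, table)
    pairs = _paired_homologues(a, b, table)
    denom = sum(g.length_aa for g in a.genes) + sum(g.length_aa for g in b.genes)
    if denom == 0:
        raise ValueError("genomes have no genes")
    num = sum((x.length_aa + y.length_aa) * ident for x, y, ident in pairs)
    return 100.0 * num / denom


# ---------------------------------------------------------------------------
# Nucleotide-level: seed-and-extend HSP search and gNI
# ---------------------------------------------------------------------------

def _extend_seed(
    query: str, subj: str, i: int, j: int, word_size: int, xdrop: int
) -> tuple[int, int, int]:
    """Ungapped two-way X-drop extension of an exact seed.

    Returns (q_start, q_end, matches) of the best-scoring extension.
    """
    # rightward from the seed end
    best_gain = 0
    gain = 0
    right = 0
    k = 0
    while i + word_size + k < len(query) and j + word_size + k < len(subj):
        gain += MATCH_SCORE if query[i + word_size + k] == subj[j + word_size + k] else MISMATCH_SCORE
        if gain > best_gain:
            best_gain = gain
            right = k + 1
        if best_gain - gain > xdrop:
            break
        k += 1
    right_gain = best_gain
    # leftward from the seed start
    best_gain = 0
    gain = 0
    left = 0
    k = 1
    while i - k >= 0 and j - k >= 0:
        gain += MATCH_SCORE if query[i - k] == subj[j - k] else MISMATCH_SCORE
        if gain > best_gain:
            best_gain = gain
            left = k
        if best_gain - gain > xdrop:
            break
        k += 1
    q_start, q_end = i - left, i + word_size + right
    matches = sum(1 for p in range(q_start, q_end) if query[p] == subj[p - i + j])
    return q_start, q_end, matches


def _evalue(score: int, m: int, n: int) -> float:
    log_e = math.log(KA_K) + math.log(m) + math.log(n) - KA_LAMBDA * score
    if log_e < math.log(_MIN_EVALUE):
        return _MIN_EVALUE
    return math.exp(log_e)


def find_hsps(
    query: str,
    subject: str,
    word_size: int = DEFAULT_WORD_SIZE,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    xdrop: int = DEFAULT_XDROP,
) -> list[Hsp]:
    """Ungapped seed-and-extend local alignment on both strands.

    Exact ``word_size``-mers seed ungapped X-drop extensions scored
    +1/-2; overlapping extensions on one diagonal are merged greedily;
    HSPs contained in a higher-scoring HSP are dropped. E-values follow
    Karlin-Altschul E = K*m*n*exp(-lambda*S) with the fixed ungapped
    parameters above; only HSPs with E <= ``evalue_max`` are returned,
    sorted by score descending. Deterministic for fixed input.
    """
    if word_size < 7:
        raise ValueError(f"word_size must be >= 7, got {word_size}")
    if len(query) < word_size or len(subject) < word_size:
        raise ValueError("sequence shorter than word_size")
    m, n = len(query), len(subject)

    raw: list[tuple[str, int, int, int, int]] = []  # (strand, diag, q_start, q_end, matches)
    for strand in ("+", "-"):
        subj = subject if strand == "+" else reverse_complement(subject)
        index: dict[str, list[int]] = defaultdict(list)
        for j in range(n - word_size + 1):
            index[subj[j : j + word_size]].append(j)
        covered: dict[int, int] = {}  # diagonal -> q_end already extended through
        for i in range(m - word_size + 1):
            for j in index.get(query[i : i + word_size], ()):
                d = i - j
                if covered.get(d, -1) >= i + word_size:
                    continue
                qs, qe, matches = _extend_seed(query, subj, i, j, word_size, xdrop)
                covered[d] = qe
                raw.append((strand, d, qs, qe, matches))

    # Greedy merge of overlapping extensions on the same diagonal.
    merged: list[tuple[str, int, int, int, int]] = []
    by_diag: dict[tuple[str, int], list[tuple[int, int, int]]] = defaultdict(list)
    for strand, d, qs, qe, matches in raw:
        by_diag[(strand, d)].append((qs, qe, matches))
    for (strand, d), segs in by_diag.items():
        segs.sort()
        cur_s, cur_e, _ = segs[0]
        subj = subject if strand == "+" else reverse_complement(subject)
        for qs, qe, _ in segs[1:]:
            if qs <= cur_e:
                cur_e = max(cur_e, qe)
            else:
                matches = sum(1 for p in range(cur_s, cur_e) if query[p] == subj[p - d])
                merged.append((strand, d, cur_s, cur_e, matches))
                cur_s, cur_e = qs, qe
        matches = sum(1 for p in range(cur_s, cur_e) if query[p] == subj[p - d])
        merged.append((strand, d, cur_s, cur_e, matches))

    hsps: list[Hsp] = []
    for strand, d, qs, qe, matches in merged:
        length = qe - qs
        score = MATCH_SCORE * matches + MISMATCH_SCORE * (length - matches)
        if score <= 0:
            continue
        ev = _evalue(score, m, n)
        if ev > evalue_max:
            continue
        js, je = qs - d, qe - d  # subject interval in strand space
        if strand == "+":
            s_start, s_end = js, je
        else:
            s_start, s_end = n - je, n - js
        hsps.append(
            Hsp(
                q_start=qs,
                q_end=qe,
                s_start=s_start,
                s_end=s_end,
                identities=matches,
                strand=strand,
                evalue=ev,
                score=score,
            )
        )

    # Drop HSPs fully contained (query and subject) in a higher-scoring one.
    hsps.sort(key=lambda h: (-h.score, h.q_start, h.s_start, h.strand))
    kept: list[Hsp] = []
    for h in hsps:
        contained = any(
            k.strand == h.strand
            and k.q_start <= h.q_start
            and h.q_end <= k.q_end
            and k.s_start <= h.s_start
            and h.s_end <= k.s_end
            and (k.q_start, k.q_end, k.s_start, k.s_end)
            != (h.q_start, h.q_end, h.s_start, h.s_end)
            for k in kept
        )
        if not contained:
            kept.append(h)
    return kept


def _covered_identity_sum(
    intervals: list[tuple[int, int, int]], genome_len: int
) -> float:
    """Sum identities over a genome with overlaps resolved.

    ``intervals`` are (start, end, identities) projections of HSPs onto
    one genome. Fragments are taken in decreasing identity-fraction
    order; where an interval overlaps already-claimed positions, its
    identities are pro-rated over the uncovered remainder.
    """
    intervals = sorted(
        intervals, key=lambda t: (-(t[2] / (t[1] - t[0])), t[0], t[1])
    )
    claimed: list[tuple[int, int]] = []
    total = 0.0
    for start, end, ident in intervals:
        length = end - start
        uncovered = length
        for cs, ce in claimed:
            lo, hi = max(start, cs), min(end, ce)
            if lo < hi:
                uncovered -= hi - lo
        if uncovered > 0:
            total += ident * uncovered / length
            claimed.append((start, end))
            # normalize claimed list
            claimed.sort()
            norm: list[tuple[int, int]] = []
            for s, e in claimed:
                if norm and s <= norm[-1][1]:
                    norm[-1] = (norm[-1][0], max(norm[-1][1], e))
                else:
                    norm.append((s, e))
            claimed = norm
    return min(total, float(genome_len))


def gni(
    a: GenomeRecord,
    b: GenomeRecord,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    word_size: int = DEFAULT_WORD_SIZE,
) -> float:
    """Genome-wide nucleotide identity (percent).

    HSPs are found in both query/subject roles, projected onto each
    genome with overlap resolution favouring higher-identity fragments,
    and the identical-base counts are normalized over both genome
    lengths: gNI = 100 x (id_a + id_b) / (len_a + len_b). Returns 0 when
    no HSP passes the E-value filter.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("empty genome sequence")
    if a.genome_id == b.genome_id and a.sequence == b.sequence:
        return 100.0
    hsps_ab = find_hsps(a.sequence, b.sequence, word_size=word_size, evalue_max=evalue_max)
    hsps_ba = find_hsps(b.sequence, a.sequence, word_size=word_size, evalue_max=evalue_max)

    proj_a = [(h.q_start, h.q_end, h.identities) for h in hsps_ab] + [
        (h.s_start, h.s_end, h.identities) for h in hsps_ba
    ]
    proj_b = [(h.q_start, h.q_end, h.identities) for h in hsps_ba] + [
        (h.s_start, h.s_end, h.identities) for h in hsps_ab
    ]
    if not proj_a and not proj_b:
        return 0.0
    id_a = _covered_identity_sum(proj_a, len(a.sequence))
    id_b = _covered_identity_sum(proj_b, len(b.sequence))
    return 100.0 * (id_a + id_b) / (len(a.sequence) + len(b.sequence))


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

_METRIC_NAMES = ("peq", "gcs", "gni", "aai")


def pairwise_matrix(
    genomes: Sequence[GenomeRecord],
    metric: str,
    phams: Optional[Sequence[Pham]] = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    word_size: int = DEFAULT_WORD_SIZE,
) -> SimilarityMatrix:
    """Compute one metric for every genome pair (upper triangle, mirrored)."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    if metric not in _METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRIC_NAMES}")

    table = _resolve_table(phams)
    n = len(genomes)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genomes[i], genomes[j]
            if metric == "gcs":
                v = gcs(a, b, table)
            elif metric == "peq":
                v = peq(a, b, table)
            elif metric == "aai":
                v = aai_shared(a, b, table)[0]
            else:
                v = gni(a, b, evalue_max=evalue_max, word_size=word_size)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids, values, metric=metric)


def compare_pair(
    a: GenomeRecord,
    b: GenomeRecord,
    phams=None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> PairwiseSimilarity:
    """All four similarity values for one genome pair."""
    table = _resolve_table(phams)
    return PairwiseSimilarity(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        gcs=gcs(a, b, table),
        aai=aai_shared(a, b, table)[0],
        peq=peq(a, b, table),
        gni=gni(a, b, evalue_max=evalue_max),
    )
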