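"""Hierarchical taxonomy gap-filling and metric/rank concordance.

Viral taxonomy ranks used here, lowest to highest: species, genus,
subfamily, family. The ranks form a tree, so two genomes sharing a lower
rank implicitly share all higher ranks even when those are unnamed; the
gap-fill operation materializes that implication with deterministic
placeholder taxa so that pair-counting at every rank is well defined.

Concordance analysis partitions genome pairs by co-membership at each
rank and summarizes a similarity matrix over each partition (histograms
in width-5 bins on [0, 100], fraction of pairs at >= 50, fraction at
exactly 0 — "no detectable similarity" is encoded as exactly 0 after
E-value filtering), plus an optional least-squares fit between two
metrics (canonically PEQ versus gNI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import SimilarityMatrix

RANKS = ("species", "genus", "subfamily", "family")  # low to high
HIST_BIN_EDGES = np.arange(0.0, 105.0, 5.0)  # [0,5),[5,10)...[95,100]


class TaxonomyError(ValueError):
    """Inconsistent taxonomy: one taxon under two different parents."""


@dataclass
class TaxonomyAssignment:
    """Per-genome ranks, possibly partial, with per-rank provenance.

    ``filled_from`` maps each rank to 'given', 'gap_filled', or 'none'.
    """

    genome_id: str
    species: Optional[str] = None
    genus: Optional[str] = None
    subfamily: Optional[str] = None
    family: Optional[str] = None
    filled_from: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.filled_from:
            self.filled_from = {
                r: ("given" if getattr(self, r) else "none") for r in RANKS
            }

    def get(self, rank: str) -> Optional[str]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)


def read_taxonomy_tsv(path: str) -> list[TaxonomyAssignment]:
    """Read the 5-column taxonomy TSV (empty field = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["genome_id", *RANKS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing taxonomy columns {missing}")
    return [
        TaxonomyAssignment(
            genome_id=row["genome_id"],
            **{r: (row[r] or None) for r in RANKS},
        )
        for _, row in df.iterrows()
    ]


def write_taxonomy_tsv(assignments: Sequence[TaxonomyAssignment], path: str) -> None:
    rows = [
        {"genome_id": a.genome_id, **{r: a.get(r) or "" for r in RANKS}}
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def gapfill_ranks(assignments: Sequence[TaxonomyAssignment]) -> list[TaxonomyAssignment]:
    """Fill unnamed higher ranks so co-membership propagates upward.

    For every named taxon at rank r whose parent rank is unnamed, the
    parent is taken from any co-member that names it, otherwise a
    deterministic placeholder ``unnamed_<parent_rank>_<taxon>`` is
    created. Given names are never overwritten; a taxon listed under two
    different named parents raises :class:`TaxonomyError`. Idempotent.
    """
    out = [
        TaxonomyAssignment(
            genome_id=a.genome_id,
            species=a.species,
            genus=a.genus,
            subfamily=a.subfamily,
            family=a.family,
            filled_from=dict(a.filled_from),
        )
        for a in assignments
    ]
    for lo, hi in zip(RANKS, RANKS[1:]):
        parent_of: dict[str, str] = {}
        for a in out:  # learn parents from rows naming both ranks
            taxon, parent = a.get(lo), a.get(hi)
            if taxon and parent:
                if taxon in parent_of and parent_of[taxon] != parent:
                    raise TaxonomyError(
                        f"{lo} {taxon!r} listed under two {hi} parents: "
                        f"{parent_of[taxon]!r} and {parent!r}"
                    )
                parent_of[taxon] = parent
        for a in out:
            taxon = a.get(lo)
            if taxon and not a.get(hi):
                parent = parent_of.get(taxon)
                if parent is None:
                    parent = f"unnamed_{hi}_{taxon}"
                    parent_of[taxon] = parent
                setattr(a, hi, parent)
                a.filled_from[hi] = "gap_filled"
    return out


def _group_pairs(
    matrix: SimilarityMatrix, taxonomy: Sequence[TaxonomyAssignment], rank: str
) -> list[tuple[str, str]]:
    by_id = {a.genome_id: a for a in taxonomy}
    missing = [g for g in matrix.ids if g not in by_id]
    if missing:
        raise ValueError(f"genomes missing from taxonomy: {missing}")
    groups: dict[str, list[str]] = {}
    for g in matrix.ids:
        taxon = by_id[g].get(rank)
        if taxon is None:
            continue  # unnamed and unfillable: contributes no intra-rank pairs
        groups.setdefault(taxon, []).append(g)
    pairs: list[tuple[str, str]] = []
    for members in groups.values():
        pairs.extend(combinations(sorted(members), 2))
    return sorted(pairs)


def intra_rank_values(
    matrix: SimilarityMatrix, taxonomy: Sequence[TaxonomyAssignment], rank: str
) -> list[float]:
    """Matrix values for unordered genome pairs co-assigned at ``rank``.

    Self-pairs are excluded; the pair count equals the sum over taxa of
    C(n_taxon, 2).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    return [matrix.value(a, b) for a, b in _group_pairs(matrix, taxonomy, rank)]


def rank_histogram(values: Sequence[float]) -> pd.DataFrame:
    """Histogram in width-5 bins [0,5), [5,10), ..., [95,100]."""
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=HIST_BIN_EDGES)
    return pd.DataFrame(
        {
            "bin_low": HIST_BIN_EDGES[:-1],
            "bin_high": HIST_BIN_EDGES[1:],
            "count": counts,
        }
    )


def peq_vs_gni_fit(
    peq_matrix: SimilarityMatrix, gni_matrix: SimilarityMatrix
) -> dict[str, float]:
    """Least-squares fit of PEQ against gNI over all unordered pairs.

    Returns slope, intercept, Pearson r_squared, and the pair count.
    """
    if list(peq_matrix.ids) != list(gni_matrix.ids):
        raise ValueError("matrices cover different genome sets")
    n = len(peq_matrix.ids)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(gni_matrix.values[i, j])
            ys.append(peq_matrix.values[i, j])
    if len(set(xs)) < 2:
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        fit = stats.linregress(xs, ys)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r2),
        "n_pairs": len(xs),
    }


def concordance_summary(
    matrix: SimilarityMatrix,
    taxonomy: Sequence[TaxonomyAssignment],
    peq_matrix: Optional[SimilarityMatrix] = None,
) -> dict:
    """Per-rank concordance between a similarity matrix and the taxonomy.

    For each rank: pair count, width-5 histogram, fraction of intra-rank
    pairs with value >= 50, fraction with value exactly 0. When a second
    (PEQ) matrix is supplied, also returns scatter data and the
    least-squares PEQ-vs-gNI fit.
    """
    per_rank: dict[str, dict] = {}
    for rank in RANKS:
        values = np.asarray(intra_rank_values(matrix, taxonomy, rank), dtype=float)
        n_pairs = len(values)
        per_rank[rank] = {
            "n_pairs": n_pairs,
            "histogram": rank_histogram(values),
            "frac_ge_50": float((values >= 50).mean()) if n_pairs else float("nan"),
            "frac_zero": float((values == 0).mean()) if n_pairs else float("nan"),
        }
    out: dict = {"ranks": per_rank, "metric": matrix.metric}
    if peq_matrix is not None:
        out["fit"] = peq_vs_gni_fit(peq_matrix, matrix)
        n = len(matrix.ids)
        out["scatter"] = pd.DataFrame(
            [
                {
                    "genome_a": matrix.ids[i],
                    "genome_b": matrix.ids[j],
                    "gni": matrix.values[i, j],
                    "peq": peq_matrix.values[i, j],
                }
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )
    return out


def write_concordance(summary: dict, out_dir: str) -> None:
    """Write concordance_<rank>.tsv, histogram_<rank>.tsv, peq_vs_gni.tsv."""
    import os

    for rank, info in summary["ranks"].items():
        pd.DataFrame(
            [
                {
                    "rank": rank,
                    "n_pairs": info["n_pairs"],
                    "frac_ge_50": info["frac_ge_50"],
                    "frac_zero": info["frac_zero"],
                }
            ]
        ).to_csv(os.path.join(out_dir, f"concordance_{rank}.tsv"), sep="\t", index=False)
        info["histogram"].to_csv(
            os.path.join(out_dir, f"histogram_{rank}.tsv"), sep="\t", index=False
        )
    if "scatter" in summary:
        summary["scatter"].to_csv(
            os.path.join(out_dir, "peq_vs_gni.tsv"), sep="\t", index=False
        )
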