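"""Clonotype finalisation and reporting.

Turns CAST partitions into clonotypes (consensus CDR3, read support,
within-chain frequency, V/J assignment), maps D genes onto IGH clonotypes
by longest exact shared nucleotide substring, and writes the deterministic
clonotype TSV (optionally with AIRR-rearrangement-style column aliases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cast import (
    ClusterPartition,
    consensus_gene_set,
    consensus_nt_witness,
)
from .germline import GermlineIndex, GermlineSegment

logger = logging.getLogger(__name__)

MIN_D_MATCH_NT = 5

COLUMNS = [
    "chain",
    "cdr3_aa",
    "cdr3_nt",
    "count",
    "frequency",
    "v_genes",
    "d_gene",
    "j_genes",
]
AIRR_ALIASES = {
    "cdr3_aa": "junction_aa",
    "cdr3_nt": "junction",
    "count": "duplicate_count",
    "v_genes": "v_call",
    "d_gene": "d_call",
    "j_genes": "j_call",
    "chain": "locus",
}


@dataclass
class Clonotype:
    """A consensus CDR3 with read support and V(D)J assignment."""

    chain: str
    cdr3_aa: str
    cdr3_nt: Optional[str]
    count: int
    frequency: float = 0.0
    v_genes: list[str] = field(default_factory=list)
    d_gene: Optional[str] = None
    j_genes: list[str] = field(default_factory=list)


def map_d_gene(
    cdr3_nt: Optional[str],
    d_segments: Sequence[GermlineSegment],
    min_match: int = MIN_D_MATCH_NT,
) -> Optional[str]:
    """D gene sharing the longest exact substring with the CDR3 interior.

    The interior excludes the anchor codons at either end; matches shorter
    than ``min_match`` nt are noise (D genes are 10-30 nt) and give None.
    Ties resolve to the alphabetically first gene id.
    """
    if not cdr3_nt or len(cdr3_nt) <= 6 or not d_segments:
        return None
    interior = cdr3_nt[3:-3]
    best_id: Optional[str] = None
    best_len = min_match - 1
    for seg in sorted(d_segments, key=lambda s: s.id):
        longest = _longest_shared_substring(interior, seg.nt_seq)
        if longest > best_len:
            best_len = longest
            best_id = seg.id
    return best_id


def _longest_shared_substring(a: str, b: str) -> int:
    """Length of the longest common substring of ``a`` and ``b``.

    Binary search over the length; substring sharing is monotone in k."""
    lo, hi, best = 1, min(len(a), len(b)), 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if _shares_kmer(a, b, mid):
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if k <= 0 or k > min(len(a), len(b)):
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def build_clonotypes(
    partitions_by_chain: dict[str, list[ClusterPartition]],
    index: Optional[GermlineIndex] = None,
) -> list[Clonotype]:
    """Finalise CAST partitions into frequency-normalised clonotypes."""
    clonotypes: list[Clonotype] = []
    for chain, partitions in sorted(partitions_by_chain.items()):
        chain_total = sum(p.total_count for p in partitions)
        for part in partitions:
            nt = consensus_nt_witness(part)
            d_gene = None
            if chain == "IGH" and index is not None:
                d_gene = map_d_gene(nt, index.d_segments.get("IGH", []))
            clonotypes.append(
                Clonotype(
                    chain=chain,
                    cdr3_aa=part.consensus_aa,
                    cdr3_nt=nt,
                    count=part.total_count,
                    frequency=part.total_count / chain_total if chain_total else 0.0,
                    v_genes=consensus_gene_set(part, "v"),
                    d_gene=d_gene,
                    j_genes=consensus_gene_set(part, "j"),
                )
            )
    clonotypes.sort(key=lambda c: (c.chain, -c.count, c.cdr3_aa))
    return clonotypes


def clonotype_frame(clonotypes: Sequence[Clonotype], airr: bool = False) -> pd.DataFrame:
    rows = [
        {
            "chain": c.chain,
            "cdr3_aa": c.cdr3_aa,
            "cdr3_nt": c.cdr3_nt or "",
            "count": c.count,
            "frequency": c.frequency,
            "v_genes": ",".join(c.v_genes),
            "d_gene": c.d_gene or "",
            "j_genes": ",".join(c.j_genes),
        }
        for c in clonotypes
    ]
    frame = pd.DataFrame(rows, columns=COLUMNS)
    if airr:
        frame = frame.rename(columns=AIRR_ALIASES)
    return frame


def write_clonotype_table(
    clonotypes: Sequence[Clonotype], path: str, airr: bool = False
) -> None:
    """Deterministic TSV report, sorted by (chain, -count, cdr3_aa)."""
    clonotype_frame(clonotypes, airr=airr).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_clonotype_table(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"cdr3_nt": str, "d_gene": str})
    reverse = {v: k for k, v in AIRR_ALIASES.items()}
    return frame.rename(columns=reverse)
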