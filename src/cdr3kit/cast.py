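"""PCR/sequencing error correction via CAST clustering.

Assembled CDR3 amino-acid sequences form a complete weighted graph: nodes
are distinct sequences weighted by their supporting read counts, edge
affinities are the inverse Levenshtein distance. CAST (cluster-affinity
search technique) grows one partition at a time from the unassigned node of
maximal weighted degree, alternately admitting every node whose mean
affinity to the partition reaches the threshold tau and expelling every
member whose mean affinity to the rest of the partition falls below it.
Each closed partition is reported as one clonotype through its
count-weighted consensus sequence.

Low tau collapses everything into one cluster; tau > 1 leaves every node a
singleton (affinities never exceed 1). The default tau = 0.25 merges
sequences within edit distance 4 of a cluster on average -- satellites one
or two errors away from an abundant parent -- while keeping bona fide
distinct clonotypes apart.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assembly import Cdr3Candidate, levenshtein

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.25
_MAX_PASSES = 100


@dataclass
class Cdr3Node:
    """One distinct assembled CDR3 with its read support."""

    aa_seq: str
    count: int
    chain: str = ""
    v_support: Counter = field(default_factory=Counter)
    j_support: Counter = field(default_factory=Counter)
    nt_witness: Counter = field(default_factory=Counter)

    @property
    def v_hits(self) -> list[str]:
        return sorted(self.v_support)

    @property
    def j_hits(self) -> list[str]:
        return sorted(self.j_support)


@dataclass
class ClusterPartition:
    members: list[Cdr3Node]
    consensus_aa: str = ""
    total_count: int = 0


def aggregate_candidates(candidates: Sequence[Cdr3Candidate]) -> dict[str, list[Cdr3Node]]:
    """Collapse per-read candidates into per-chain weighted nodes.

    Identical reads aggregate into counts here, so node sequences are
    unique within each chain's graph and affinities are always defined.
    """
    nodes: dict[tuple[str, str], Cdr3Node] = {}
    for cand in candidates:
        key = (cand.chain, cand.core_aa)
        node = nodes.get(key)
        if node is None:
            node = nodes[key] = Cdr3Node(aa_seq=cand.core_aa, count=0, chain=cand.chain)
        node.count += 1
        node.v_support.update(cand.v_hits)
        node.j_support.update(cand.j_hits)
        node.nt_witness[cand.core_nt] += 1
    by_chain: dict[str, list[Cdr3Node]] = {}
    for (chain, _), node in sorted(nodes.items()):
        by_chain.setdefault(chain, []).append(node)
    return by_chain


def affinity(a: str, b: str) -> float:
    """Inverse Levenshtein distance between two distinct sequences."""
    d = levenshtein(a, b)
    if d == 0:
        raise ValueError("affinity undefined for identical sequences")
    return 1.0 / d


def cast_cluster(
    nodes: Sequence[Cdr3Node], tau: float = DEFAULT_TAU
) -> list[ClusterPartition]:
    """Partition the CDR3 graph with CAST at affinity threshold ``tau``.

    The seed of each partition is the unassigned node with maximal
    count-weighted affinity sum to the other unassigned nodes (the only
    meaningful notion of "max degree" in a complete graph); ties break by
    higher count, then lexicographic sequence. Mean affinities are
    count-weighted. A pass cap guards against oscillation.
    """
    if not nodes:
        return []
    n = len(nodes)
    aff = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a = affinity(nodes[i].aa_seq, nodes[j].aa_seq)
            aff[i][j] = aff[j][i] = a

    unassigned = set(range(n))
    partitions: list[ClusterPartition] = []
    while unassigned:
        seed = max(
            unassigned,
            key=lambda i: (
                sum(nodes[j].count * aff[i][j] for j in unassigned if j != i),
                nodes[i].count,
                _neg(nodes[i].aa_seq),
            ),
        )
        members = {seed}
        candidates = set(unassigned) - {seed}
        seen_states: set[frozenset] = set()
        for _pass in range(_MAX_PASSES):
            state = frozenset(members)
            if state in seen_states:
                logger.debug("CAST add/remove cycle; closing partition")
                break
            seen_states.add(state)
            changed = False
            add = {
                i
                for i in candidates
                if _mean_affinity(i, members, nodes, aff) >= tau
            }
            if add:
                members |= add
                candidates -= add
                changed = True
            if len(members) > 1:
                drop = {
                    i
                    for i in members
                    if _mean_affinity(i, members - {i}, nodes, aff) < tau
                }
                if drop == members:
                    drop = set()  # keep at least the seed's cluster nonempty
                if drop:
                    members -= drop
                    candidates |= drop
                    changed = True
            if not changed:
                break
        else:
            logger.warning("CAST pass cap reached; closing partition as-is")
        part = ClusterPartition(members=[nodes[i] for i in sorted(members)])
        part.total_count = sum(m.count for m in part.members)
        part.consensus_aa = weighted_consensus(part)
        partitions.append(part)
        unassigned -= members
    return partitions


def _mean_affinity(i: int, group: set, nodes: Sequence[Cdr3Node], aff) -> float:
    total_w = sum(nodes[j].count for j in group)
    if total_w == 0:
        return 0.0
    return sum(nodes[j].count * aff[i][j] for j in group) / total_w


class _neg(str):
    def __lt__(self, other):
        return str.__gt__(self, other)


def weighted_consensus(partition: ClusterPartition) -> str:
    """Count-weighted consensus CDR3 of a partition.

    Restricted to the length class with the largest total count (ties ->
    shorter length); per-position count-weighted majority within that
    class, ties broken alphabetically.
    """
    members = partition.members
    if not members:
        raise ValueError("empty partition")
    by_len: Counter = Counter()
    for m in members:
        by_len[len(m.aa_seq)] += m.count
    length = min(
        by_len, key=lambda ln: (-by_len[ln], ln)
    )
    group = [m for m in members if len(m.aa_seq) == length]
    consensus = []
    for pos in range(length):
        votes: Counter = Counter()
        for m in group:
            votes[m.aa_seq[pos]] += m.count
        consensus.append(min(votes, key=lambda r: (-votes[r], r)))
    return "".join(consensus)


def consensus_gene_set(partition: ClusterPartition, which: str = "v") -> list[str]:
    """Most-supported gene ids across a partition (weighted majority)."""
    support: Counter = Counter()
    for m in partition.members:
        src = m.v_support if which == "v" else m.j_support
        for gene, c in src.items():
            support[gene] += c
    if not support:
        return []
    top = max(support.values())
    return sorted(g for g, c in support.items() if c == top)


def consensus_nt_witness(partition: ClusterPartition) -> Optional[str]:
    """Nucleotide core of the best-supported member sequence (highest count,
    then most frequent witness, then lexicographic)."""
    best_member = max(
        partition.members, key=lambda m: (m.count, _neg(m.aa_seq))
    )
    if not best_member.nt_witness:
        return None
    return min(
        best_member.nt_witness, key=lambda nt: (-best_member.nt_witness[nt], nt)
    )
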