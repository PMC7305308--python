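"""End-to-end orchestration: candidate reads -> clonotype table.

Order of operations: germline k-mer screen (read extraction) -> quality /
complexity filter -> stage-1 full-CDR3 detection and partial-read
classification -> optional stage-2 overlap merging -> per-chain CAST error
correction -> clonotype finalisation. The screen and the quality filter
are independent per-read predicates, so applying the cheap screen first
changes nothing but the running time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import assembly, cast
from .annotate import Clonotype, build_clonotypes
from .assembly import Cdr3Candidate, GermlineKmerScreen, STAGE2_MAX_READ_LENGTH
from .cast import ClusterPartition
from .germline import GermlineIndex
from .intake import CandidateRead, quality_filter

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable knobs of a full assembly run."""

    tau: float = cast.DEFAULT_TAU
    use_cast: bool = True
    #: None = auto: stage 2 on iff observed read length <= 50 bp.
    use_stage2: Optional[bool] = None
    allow_stop: bool = False
    min_mean_quality: float = 20.0
    min_entropy: float = 1.0
    rrna_fasta: Optional[str] = None


@dataclass
class PipelineResult:
    clonotypes: list[Clonotype]
    candidates: list[Cdr3Candidate]
    detected_read_ids: set[str]
    n_input_reads: int
    n_screened: int
    n_merged: int
    partitions_by_chain: dict[str, list[ClusterPartition]] = field(default_factory=dict)

    def clonotype_set(self, chain: Optional[str] = None) -> set[str]:
        return {
            c.cdr3_aa for c in self.clonotypes if chain is None or c.chain == chain
        }


def run_pipeline(
    reads: Iterable[CandidateRead],
    index: GermlineIndex,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    screen = GermlineKmerScreen(index)
    n_input = 0
    screened: list[CandidateRead] = []
    max_len = 0
    for read in reads:
        n_input += 1
        if len(read.nt_seq) > max_len:
            max_len = len(read.nt_seq)
        if screen.hits(read.nt_seq):
            screened.append(read)
    screened = list(
        quality_filter(
            screened,
            min_mean_quality=cfg.min_mean_quality,
            min_entropy=cfg.min_entropy,
            rrna_fasta=cfg.rrna_fasta,
        )
    )
    detected_ids = {r.read_id for r in screened}

    v_only, j_only, candidates = assembly.classify_partials(
        screened, index, allow_stop=cfg.allow_stop
    )
    use_stage2 = (
        cfg.use_stage2
        if cfg.use_stage2 is not None
        else max_len <= STAGE2_MAX_READ_LENGTH
    )
    merged: list[Cdr3Candidate] = []
    if use_stage2:
        merged = assembly.stage2_merge(
            v_only, j_only, index, allow_stop=cfg.allow_stop
        )
        candidates = candidates + merged
    logger.info(
        "pipeline: %d reads in, %d screened, %d stage-1 candidates, %d merged",
        n_input,
        len(screened),
        len(candidates) - len(merged),
        len(merged),
    )

    nodes_by_chain = cast.aggregate_candidates(candidates)
    partitions_by_chain: dict[str, list[ClusterPartition]] = {}
    for chain, nodes in nodes_by_chain.items():
        if cfg.use_cast:
            partitions_by_chain[chain] = cast.cast_cluster(nodes, tau=cfg.tau)
        else:
            singletons = []
            for node in nodes:
                part = ClusterPartition(
                    members=[node], consensus_aa=node.aa_seq, total_count=node.count
                )
                singletons.append(part)
            partitions_by_chain[chain] = singletons
    clonotypes = build_clonotypes(partitions_by_chain, index)
    return PipelineResult(
        clonotypes=clonotypes,
        candidates=candidates,
        detected_read_ids=detected_ids,
        n_input_reads=n_input,
        n_screened=len(screened),
        n_merged=len(merged),
        partitions_by_chain=partitions_by_chain,
    )
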