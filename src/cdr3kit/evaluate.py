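"""Scoring assembled repertoires against simulation truth.

Clonotype-level exact-match scoring: TP is the number of assembled CDR3
amino-acid sequences exactly matching a simulated one, FN the simulated
sequences missed, FP the assembled sequences matching nothing. Recall =
TP/(TP+FN), precision = TP/(TP+FP), F-score their harmonic mean. Also
provides read-extraction recall against the truth manifest and the
simulate -> assemble -> score sweep over read lengths and coverages.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .germline import GermlineIndex
from .intake import CandidateRead
from .pipeline import PipelineConfig, run_pipeline
from .simulate import SimConfig, simulate_reads, simulate_transcripts, truth_manifest

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    tp: int
    fn: int
    fp: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def score(assembled: Iterable[str], truth: Iterable[str]) -> EvalResult:
    """Exact-match clonotype scoring; duplicates collapse before counting."""
    assembled_set, truth_set = set(assembled), set(truth)
    if not truth_set:
        raise ValueError("truth set is empty")
    tp = len(assembled_set & truth_set)
    return EvalResult(tp=tp, fn=len(truth_set - assembled_set), fp=len(assembled_set - truth_set))


def read_extraction_recall(candidate_ids: set[str], manifest: pd.DataFrame) -> float:
    """Fraction of junction-flagged receptor reads present in the candidate
    read set."""
    flagged = manifest.loc[manifest["junction_flag"] == 1, "read_id"]
    if flagged.empty:
        raise ValueError("manifest flags no junction-spanning reads")
    return float(flagged.isin(candidate_ids).mean())


def _as_candidates(sim_reads) -> list[CandidateRead]:
    return [
        CandidateRead(read_id=r.id, nt_seq=r.seq, origin="direct_fastq", mate=r.mate)
        for r in sim_reads
    ]


def run_cell(
    index: GermlineIndex,
    sim_cfg: SimConfig,
    pipe_cfg: Optional[PipelineConfig] = None,
) -> tuple[EvalResult, pd.DataFrame]:
    """One simulate -> assemble -> score cycle; returns the evaluation and
    the per-cell summary row."""
    transcripts = simulate_transcripts(sim_cfg, index)
    reads = simulate_reads(transcripts, sim_cfg)
    result = run_pipeline(_as_candidates(reads), index, pipe_cfg)
    truth = {tx.true_cdr3_aa for tx in transcripts}
    chains = {tx.chain for tx in transcripts}
    assembled = {c.cdr3_aa for c in result.clonotypes if c.chain in chains}
    ev = score(assembled, truth)
    row = pd.DataFrame(
        [
            {
                "read_length": sim_cfg.read_length,
                "coverage": sim_cfg.coverage,
                "seed": sim_cfg.seed,
                "n_transcripts": sim_cfg.n_transcripts,
                "n_reads": len(reads),
                "tp": ev.tp,
                "fn": ev.fn,
                "fp": ev.fp,
                "recall": ev.recall,
                "precision": ev.precision,
                "f_score": ev.f_score,
            }
        ]
    )
    return ev, row


def sweep(
    index: GermlineIndex,
    read_lengths: Sequence[int] = (50, 75, 100),
    coverages: Sequence[float] = (8, 16, 32),
    seeds: Sequence[int] = (1, 2, 3),
    base_cfg: Optional[SimConfig] = None,
    pipe_cfg: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Precision/recall/F grid over (read length x coverage x seed)."""
    base = base_cfg or SimConfig(seed=0, n_transcripts=200, chains=("IGH",))
    rows = []
    for l in read_lengths:
        for c in coverages:
            for seed in seeds:
                cfg = dataclasses.replace(
                    base, read_length=int(l), coverage=float(c), seed=int(seed)
                )
                _, row = run_cell(index, cfg, pipe_cfg)
                rows.append(row)
                logger.info(
                    "sweep l=%d c=%g seed=%d: recall=%.3f precision=%.3f",
                    l, c, seed,
                    float(row["recall"].iloc[0]),
                    float(row["precision"].iloc[0]),
                )
    return pd.concat(rows, ignore_index=True)
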