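"""Ground-truth simulator for the validation framework.

Generates (i) a miniature synthetic germline with the anatomy the assembler
relies on -- V segments ending in a conserved cysteine followed by a short
germline-templated tail, J segments beginning with a few templated residues
before the conserved F/W and a framework-4 tail after it, and an IGH D-gene
pool -- (ii) germline-recombined Ig transcripts with non-templated junction
insertions and power-law clone frequencies, (iii) paired-end reads with a
substitution error model, and (iv) RNA-Seq-like mixtures of receptor reads
with transcriptomic decoy reads. Every artefact is reproducible from the
seed, and a truth manifest records each read's transcript of origin and
whether it overlaps the recombination junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .germline import (
    CODON_TO_AA,
    GermlineIndex,
    GermlineSegment,
    locate_anchor,
    revcomp,
    translate_nt,
)

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Codon choices per amino acid, for reverse translation of synthetic
# germline frameworks (alphabetical, deterministic).
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class SimulatedTranscript:
    """A ground-truth recombined Ig transcript.

    ``full_nt == V + n1 + D + n2 + J`` for IGH and ``V + n1 + J`` for the
    light chains. ``junction_start/junction_end`` delimit the non-templated
    region (insertions plus D) in transcript coordinates;
    ``cdr3_start/cdr3_end`` delimit the nucleotides encoding the CDR3
    (conserved C through conserved F/W, codon-inclusive).
    """

    id: str
    chain: str
    v_id: str
    d_id: Optional[str]
    j_id: str
    n1_nt: str
    n2_nt: str
    full_nt: str
    true_cdr3_aa: str
    cdr3_start: int
    cdr3_end: int
    junction_start: int
    junction_end: int
    abundance: float = 0.0


@dataclass
class SimRead:
    """One simulated mate read with its truth annotations."""

    id: str
    mate: int
    seq: str
    transcript_id: Optional[str]
    start: int
    contains_junction: bool


@dataclass
class SimConfig:
    """Simulation design parameters.

    ``coverage`` is the expected per-base depth contributed by all mates of
    a transcript at the mean clone frequency; ``insertion_mean``/``sd``
    parameterise the total non-templated insertion per transcript (split
    between the two IGH junctions); ``power_exponent`` shapes the power-law
    clone-frequency distribution (0 = uniform); ``mixture_ratio`` is the
    number of transcriptomic decoy reads per receptor-derived read.
    """

    seed: int
    n_transcripts: int = 1000
    read_length: int = 75
    coverage: float = 8.0
    error_rate: float = 0.001
    mixture_ratio: float = 3600.0
    power_exponent: float = 1.0
    insertion_mean: float = 15.0
    insertion_sd: float = 4.0
    chains: Sequence[str] = ("IGH", "IGK", "IGL")
    abundance_weighted: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    min_cdr3_aa: int = 4
    max_cdr3_aa: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("n_transcripts", "read_length", "coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Synthetic germline fixture
# ---------------------------------------------------------------------------

def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[res][rng.integers(len(_AA_TO_CODONS[res]))] for res in aa
    )


def _random_aa(n: int, rng: np.random.Generator, forbid: str = "") -> str:
    alphabet = [a for a in AA_ALPHABET if a not in forbid]
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def _random_nt(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


# Chain architecture of the synthetic fixture: framework length before the
# V anchor, V tail after the anchor (germline-templated CDR3 start), J
# residues before the anchor (germline-templated CDR3 end), J framework-4
# tail after the anchor, and counts of genes per class.
_CHAIN_DESIGN = {
    "IGH": dict(v_pre=91, v_post=2, j_pre=4, j_post="GQGTLVTVSS", n_v=8, n_j=4, n_d=6),
    "IGK": dict(v_pre=89, v_post=4, j_pre=2, j_post="GQGTKLEIK", n_v=6, n_j=4, n_d=0),
    "IGL": dict(v_pre=89, v_post=4, j_pre=2, j_post="GGGTKLTVL", n_v=4, n_j=3, n_d=0),
}

#: Synthetic IGH D-gene lengths (nt); real D genes span roughly 11-37 nt.
_D_LENGTHS = (11, 13, 15, 17, 19, 21)


def synthetic_germline(seed: int = 0) -> list[GermlineSegment]:
    """Build the bundled miniature germline (deterministic in ``seed``).

    The segments are random in their frameworks but carry the conserved
    anchor anatomy of real Ig genes, so every loader/assembler invariant
    (last-C anchor for V, first-F/W anchor for J) holds by construction.
    """
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    for chain, design in _CHAIN_DESIGN.items():
        anchor = "W" if chain == "IGH" else "F"
        for i in range(design["n_v"]):
            # last C must be the anchor: the post-anchor tail is C-free
            aa = (
                _random_aa(design["v_pre"], rng, forbid="")
                + "C"
                + _random_aa(design["v_post"], rng, forbid="C")
            )
            segments.append(
                GermlineSegment(
                    id=f"{chain}V{i + 1}-1*01",
                    chain=chain,
                    segment_class="V",
                    nt_seq=_reverse_translate(aa, rng),
                )
            )
        for i in range(design["n_j"]):
            # first F/W must be the anchor: the pre-anchor head avoids it
            aa = (
                _random_aa(design["j_pre"], rng, forbid=anchor)
                + anchor
                + design["j_post"]
            )
            segments.append(
                GermlineSegment(
                    id=f"{chain}J{i + 1}*01",
                    chain=chain,
                    segment_class="J",
                    nt_seq=_reverse_translate(aa, rng),
                )
            )
        for i in range(design["n_d"]):
            segments.append(
                GermlineSegment(
                    id=f"{chain}D{i + 1}-1*01",
                    chain=chain,
                    segment_class="D",
                    nt_seq=_random_nt(_D_LENGTHS[i % len(_D_LENGTHS)], rng),
                )
            )
    for seg in segments:
        if seg.segment_class in ("V", "J"):
            seg.anchor_pos = locate_anchor(seg)
    return segments


def write_germline_dir(segments: Iterable[GermlineSegment], out_dir: str) -> None:
    """Write segments as ``<chain><class>.fasta`` with IMGT-style headers."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    groups: dict[tuple[str, str], list[GermlineSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.chain, seg.segment_class), []).append(seg)
    for (chain, seg_class), group in sorted(groups.items()):
        path = os.path.join(out_dir, f"{chain}{seg_class}.fasta")
        with open(path, "w") as fh:
            for k, seg in enumerate(group):
                header = (
                    f"X{k:05d}|{seg.id}|Homo sapiens|F|{seg_class}-REGION|"
                    f"1..{len(seg.nt_seq)}|{len(seg.nt_seq)} nt|1| | | | |"
                )
                fh.write(f">{header}\n{seg.nt_seq}\n")


def fixture_index(seed: int = 0) -> GermlineIndex:
    """The bundled synthetic germline as a ready-to-use index."""
    return GermlineIndex.build(synthetic_germline(seed))


# ---------------------------------------------------------------------------
# Transcript simulation
# ---------------------------------------------------------------------------

def _recombine(
    cfg: SimConfig,
    index: GermlineIndex,
    chain: str,
    rng: np.random.Generator,
) -> Optional[dict]:
    """One V(D)J recombination draw; ``None`` when out of frame/invalid."""
    v = index.v_segments[chain][rng.integers(len(index.v_segments[chain]))]
    j = index.j_segments[chain][rng.integers(len(index.j_segments[chain]))]
    d = None
    if chain == "IGH":
        ds = index.d_segments[chain]
        d = ds[rng.integers(len(ds))]
    if len(v.nt_seq) % 3 != 0 or v.anchor_pos is None or j.anchor_pos is None:
        return None
    total_ins = max(0, int(round(rng.normal(cfg.insertion_mean, cfg.insertion_sd))))
    if d is not None:
        n1_len = int(rng.binomial(total_ins, 0.5))
        n2_len = total_ins - n1_len
    else:
        n1_len, n2_len = total_ins, 0
    n1 = _random_nt(n1_len, rng)
    n2 = _random_nt(n2_len, rng)
    middle = n1 + (d.nt_seq if d is not None else "") + n2
    full_nt = v.nt_seq + middle + j.nt_seq
    j_offset = len(v.nt_seq) + len(middle)
    if j_offset % 3 != 0:
        return None  # insertion shifts J out of frame
    aa = translate_nt(full_nt)
    p_c = v.anchor_pos
    j_anchor_aa = j_offset // 3 + j.anchor_pos
    if j_anchor_aa >= len(aa):
        return None
    cdr3 = aa[p_c : j_anchor_aa + 1]
    if "*" in cdr3 or "X" in cdr3:
        return None
    if not (cfg.min_cdr3_aa <= len(cdr3) <= cfg.max_cdr3_aa):
        return None
    if aa[j_anchor_aa] != ("W" if chain == "IGH" else "F"):
        return None  # junction introduced an earlier anchor-like frame shift
    return dict(
        chain=chain,
        v_id=v.id,
        d_id=d.id if d is not None else None,
        j_id=j.id,
        n1_nt=n1,
        n2_nt=n2,
        full_nt=full_nt,
        true_cdr3_aa=cdr3,
        cdr3_start=3 * p_c,
        cdr3_end=3 * (j_anchor_aa + 1),
        junction_start=len(v.nt_seq),
        junction_end=len(v.nt_seq) + len(middle),
    )


def simulate_transcripts(
    cfg: SimConfig, index: GermlineIndex
) -> list[SimulatedTranscript]:
    """Rejection-sample ``cfg.n_transcripts`` in-frame recombined transcripts.

    Segment choice is uniform per class; out-of-frame draws and draws whose
    CDR3 span contains a stop are rejected and redrawn. Clone frequencies
    follow rank^(-power_exponent), normalised, assigned in generation order.
    """
    rng = np.random.default_rng(cfg.seed)
    chains = [c for c in cfg.chains if index.v_segments.get(c)]
    if not chains:
        raise ValueError("germline index has no segments for requested chains")
    transcripts: list[SimulatedTranscript] = []
    attempts = 0
    max_attempts = max(10_000, 100 * cfg.n_transcripts)
    while len(transcripts) < cfg.n_transcripts:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection rate too high: {len(transcripts)} accepted "
                f"in {attempts} draws; check germline/insertion settings"
            )
        chain = chains[rng.integers(len(chains))]
        draw = _recombine(cfg, index, chain, rng)
        if draw is None:
            continue
        k = len(transcripts)
        transcripts.append(SimulatedTranscript(id=f"tx{k:05d}", **draw))
    ranks = np.arange(1, cfg.n_transcripts + 1, dtype=float)
    weights = ranks ** (-cfg.power_exponent)
    weights /= weights.sum()
    for tx, w in zip(transcripts, weights):
        tx.abundance = float(w)
    return transcripts


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), min(rate, 1.0))
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in positions:
        out[pos] = "ACGT"[(("ACGT".find(out[pos]) + 1 + rng.integers(3)) % 4)]
    return "".join(out)


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def simulate_reads(
    transcripts: Sequence[SimulatedTranscript], cfg: SimConfig
) -> list[SimRead]:
    """Simulate paired-end reads at the configured coverage.

    Library fragments follow a Gaussian insert-size model (mean 300 nt, sd
    50 nt -- a standard Illumina RNA-Seq library), clipped to the read and
    transcript lengths, and start uniformly on the transcript; each yields
    two mates (R2 on the reverse strand). Fragment counts are set so a
    transcript at unit clone weight receives ``coverage`` expected per-base
    depth from all mates; with ``abundance_weighted`` the count is
    additionally scaled by ``n * abundance`` (mean 1 across the repertoire).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    l = cfg.read_length
    n = len(transcripts)
    reads: list[SimRead] = []
    for tx in transcripts:
        L = len(tx.full_nt)
        if L < l:
            logger.warning("%s shorter than read length; skipped", tx.id)
            continue
        weight = n * tx.abundance if cfg.abundance_weighted else 1.0
        n_frag = int(round(cfg.coverage * L / (2 * l) * weight))
        if n_frag <= 0:
            continue
        frag_lens = np.clip(
            np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frag)), l, L
        ).astype(int)
        for i, eff_frag in enumerate(frag_lens.tolist()):
            s = int(rng.integers(0, L - eff_frag + 1))
            frag = tx.full_nt[s : s + eff_frag]
            r1 = frag[:l]
            r2 = revcomp(frag[-l:])
            r2_start = s + eff_frag - l
            for mate, seq, start in ((1, r1, s), (2, r2, r2_start)):
                reads.append(
                    SimRead(
                        id=f"{tx.id}_f{i}_{mate}",
                        mate=mate,
                        seq=_inject_errors(seq, cfg.error_rate, rng),
                        transcript_id=tx.id,
                        start=start,
                        contains_junction=_overlaps(
                            start, start + l, tx.junction_start, tx.junction_end
                        ),
                    )
                )
    return reads


def make_mixture(
    receptor_reads: Sequence[SimRead],
    cfg: SimConfig,
    decoy_source: Optional[Sequence[str]] = None,
) -> list[SimRead]:
    """Interleave receptor reads with ``mixture_ratio`` x decoy reads.

    Decoys come from ``decoy_source`` (transcript sequences) or from the
    built-in generator: random transcripts at human-like 42% GC, 500-3000 nt.
    The combined read list is shuffled deterministically from the seed.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_decoy = int(round(cfg.mixture_ratio * len(receptor_reads)))
    combined = list(receptor_reads)
    if n_decoy > 0:
        if decoy_source is None:
            pool = [
                _random_nt(int(rng.integers(500, 3001)), rng, gc=0.42)
                for _ in range(500)
            ]
        else:
            pool = [s for s in decoy_source if len(s) >= cfg.read_length]
            if not pool:
                raise ValueError("decoy source has no usable transcripts")
        l = cfg.read_length
        tx_idx = rng.integers(0, len(pool), size=(n_decoy + 1) // 2)
        for i, ti in enumerate(tx_idx.tolist()):
            src = pool[ti]
            eff = min(2 * l, len(src))
            s = int(rng.integers(0, len(src) - eff + 1))
            frag = src[s : s + eff]
            for mate, seq in ((1, frag[:l]), (2, revcomp(frag[-l:]))):
                if len(combined) - len(receptor_reads) >= n_decoy:
                    break
                combined.append(
                    SimRead(
                        id=f"decoy{i:07d}_{mate}",
                        mate=mate,
                        seq=_inject_errors(seq, cfg.error_rate, rng),
                        transcript_id=None,
                        start=s,
                        contains_junction=False,
                    )
                )
    order = rng.permutation(len(combined))
    return [combined[i] for i in order.tolist()]


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


def truth_manifest(
    transcripts: Sequence[SimulatedTranscript], reads: Sequence[SimRead]
) -> pd.DataFrame:
    """Truth table: one row per receptor-derived read."""
    by_id = {tx.id: tx for tx in transcripts}
    rows = [
        {
            "read_id": r.id,
            "transcript_id": r.transcript_id,
            "true_cdr3_aa": by_id[r.transcript_id].true_cdr3_aa,
            "chain": by_id[r.transcript_id].chain,
            "junction_flag": int(r.contains_junction),
        }
        for r in reads
        if r.transcript_id is not None
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "true_cdr3_aa", "chain", "junction_flag"]
    )


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, sep="\t", index=False)
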