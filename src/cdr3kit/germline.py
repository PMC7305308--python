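"""Germline V/D/J segment handling.

Loads immunoglobulin germline gene segments (IMGT-dialect FASTA: gap dots,
pipe-delimited headers), locates the conserved CDR3 anchor residues -- the
last cysteine of each V segment and the first phenylalanine (IGK/IGL) or
tryptophan (IGH) of each J segment -- and derives the anchor-split
substrings used by the assembler to recognise reads overlapping the V(D)J
junction.

Coordinates are 0-based, half-open throughout; only log messages use
1-based positions.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

CHAINS = ("IGH", "IGK", "IGL")
SEGMENT_CLASSES = ("V", "D", "J")

#: J-segment anchor residue per chain: tryptophan for the heavy chain,
#: phenylalanine for the light chains.
J_ANCHOR = {"IGH": "W", "IGK": "F", "IGL": "F"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate_nt(nt: str) -> str:
    """Translate frame 0 of ``nt``; codons containing anything outside
    A/C/G/T become 'X', stops become '*'. Trailing partial codon ignored."""
    return "".join(
        CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


@dataclass
class GermlineSegment:
    """One germline V, D or J gene.

    ``anchor_pos`` is the 0-based index into ``aa_seq`` of the conserved
    anchor residue (p_C for V, p_F for J); ``None`` for D segments and for
    segments whose anchor could not be located.
    """

    id: str
    chain: str
    segment_class: str
    nt_seq: str
    aa_seq: str = ""
    anchor_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.segment_class!r}")
        if self.segment_class in ("V", "J") and not self.aa_seq:
            self.aa_seq = translate_nt(self.nt_seq)

    @property
    def n_len(self) -> int:
        return len(self.aa_seq)


@dataclass
class AnchorSplit:
    """Anchor-flanking substrings of a V or J amino-acid sequence.

    For a V gene, ``pre_anchor`` is V_x = V[0, p_C) and ``post_anchor`` is
    V_y = V(p_C, n_V); for a J gene, J_x = J[0, p_F) and J_y = J(p_F, n_J).
    The anchor residue itself belongs to neither side.
    """

    pre_anchor: str
    post_anchor: str


def locate_anchor(seg: GermlineSegment) -> Optional[int]:
    """Return the anchor position of a V or J segment.

    V: index of the LAST cysteine. J: index of the FIRST phenylalanine
    (IGK/IGL) or tryptophan (IGH). Returns ``None`` when the residue is
    absent (the caller should exclude the segment with a warning).
    """
    if not seg.aa_seq:
        raise ValueError(f"{seg.id}: empty amino-acid sequence")
    if seg.segment_class == "V":
        pos = seg.aa_seq.rfind("C")
    elif seg.segment_class == "J":
        pos = seg.aa_seq.find(J_ANCHOR[seg.chain])
    else:
        raise ValueError("D segments have no CDR3 anchor")
    return None if pos < 0 else pos


def anchor_split(seg: GermlineSegment) -> AnchorSplit:
    """Split ``seg.aa_seq`` around its located anchor residue."""
    if seg.anchor_pos is None:
        raise ValueError(f"{seg.id}: anchor not located")
    p = seg.anchor_pos
    return AnchorSplit(pre_anchor=seg.aa_seq[:p], post_anchor=seg.aa_seq[p + 1 :])


def _infer_class(header: str, default: Optional[str]) -> Optional[str]:
    """Infer V/D/J from an IMGT pipe-delimited or plain header.

    IMGT headers carry the gene name in field 2 (e.g.
    ``X92343|IGHV1-2*02|Homo sapiens|F|V-REGION|...``); plain headers are
    scanned for a gene-name token such as IGHV1-2 or TRBJ2.
    """
    fields = header.split("|")
    name = fields[1] if len(fields) > 1 else fields[0]
    for token in (name, header):
        for chain in CHAINS:
            idx = token.find(chain)
            if idx >= 0 and len(token) > idx + 3 and token[idx + 3] in SEGMENT_CLASSES:
                return token[idx + 3]
    return default


def _infer_chain(header: str, default: Optional[str]) -> Optional[str]:
    for chain in CHAINS:
        if chain in header:
            return chain
    return default


def load_imgt_fasta(
    path: str,
    chain_filter: Optional[Iterable[str]] = None,
    segment_class: Optional[str] = None,
    chain: Optional[str] = None,
) -> list[GermlineSegment]:
    """Load germline segments from a FASTA file in the IMGT dialect.

    IMGT alignment gaps ('.') are stripped; records with residual non-ACGT
    bases are rejected with a warning; V/J records whose translation hits a
    stop codon at or before the anchor (pseudogenes) are excluded.
    ``segment_class``/``chain`` override header inference for plain files.

    Raises ``OSError`` for an unreadable file and ``ValueError`` when no
    usable record remains.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    wanted = set(chain_filter) if chain_filter else None
    segments: list[GermlineSegment] = []
    for record in SeqIO.parse(path, "fasta"):
        header = record.description or record.id
        nt = str(record.seq).upper().replace(".", "")
        seg_class = _infer_class(header, segment_class)
        seg_chain = _infer_chain(header, chain)
        if seg_class is None or seg_chain is None:
            logger.warning("%s: cannot infer chain/class for %r; skipped", path, header)
            continue
        if wanted and seg_chain not in wanted:
            continue
        if set(nt) - set("ACGT"):
            logger.warning("%s: %r has ambiguous bases; skipped", path, record.id)
            continue
        seg = GermlineSegment(
            id=record.id.split("|")[1] if "|" in record.id else record.id,
            chain=seg_chain,
            segment_class=seg_class,
            nt_seq=nt,
        )
        if seg_class in ("V", "J"):
            pos = locate_anchor(seg)
            if pos is None:
                logger.warning("%s: no conserved anchor in %s; excluded", path, seg.id)
                continue
            stop = seg.aa_seq.find("*")
            if 0 <= stop <= pos:
                logger.warning(
                    "%s: stop codon before anchor in %s (likely pseudogene); excluded",
                    path,
                    seg.id,
                )
                continue
            seg.anchor_pos = pos
        segments.append(seg)
    if not segments:
        raise ValueError(f"{path}: no usable germline records")
    return segments


@dataclass
class GermlineIndex:
    """Anchor-indexed germline reference for one or more chains.

    Holds, per chain, the V segments with their V_x/V_y splits, the J
    segments with their J_x/J_y splits, and the D segment pool (IGH only).
    """

    v_segments: dict[str, list[GermlineSegment]] = field(default_factory=dict)
    j_segments: dict[str, list[GermlineSegment]] = field(default_factory=dict)
    d_segments: dict[str, list[GermlineSegment]] = field(default_factory=dict)
    v_splits: dict[str, list[AnchorSplit]] = field(default_factory=dict)
    j_splits: dict[str, list[AnchorSplit]] = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        return [c for c in CHAINS if self.v_segments.get(c)]

    @classmethod
    def build(cls, segments: Sequence[GermlineSegment]) -> "GermlineIndex":
        index = cls()
        for chain in CHAINS:
            vs = [s for s in segments if s.chain == chain and s.segment_class == "V"]
            js = [s for s in segments if s.chain == chain and s.segment_class == "J"]
            ds = [s for s in segments if s.chain == chain and s.segment_class == "D"]
            if not vs and not js and not ds:
                continue
            vs.sort(key=lambda s: s.id)
            js.sort(key=lambda s: s.id)
            ds.sort(key=lambda s: s.id)
            index.v_segments[chain] = vs
            index.j_segments[chain] = js
            index.d_segments[chain] = ds
            index.v_splits[chain] = [anchor_split(s) for s in vs]
            index.j_splits[chain] = [anchor_split(s) for s in js]
        return index

    @classmethod
    def from_directory(
        cls, germline_dir: str, chains: Iterable[str] = CHAINS
    ) -> "GermlineIndex":
        """Load ``<chain><class>.fasta`` files from ``germline_dir``.

        Missing D files are tolerated for the light chains (which have no
        D segments); a chain with no V or J file is skipped with a warning.
        """
        segments: list[GermlineSegment] = []
        for chain in chains:
            classes = SEGMENT_CLASSES if chain == "IGH" else ("V", "J")
            for seg_class in classes:
                path = os.path.join(germline_dir, f"{chain}{seg_class}.fasta")
                if not os.path.exists(path):
                    logger.warning("germline file %s missing; skipped", path)
                    continue
                segments.extend(
                    load_imgt_fasta(path, segment_class=seg_class, chain=chain)
                )
        if not segments:
            raise ValueError(f"no germline segments under {germline_dir}")
        return cls.build(segments)
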