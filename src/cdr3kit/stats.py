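"""Repertoire summary statistics.

Sequencing-depth-adjusted clonotype richness (CPM: distinct clonotypes per
million raw reads), within-sample Shannon alpha-diversity in bits,
between-sample Sorensen-Dice beta-diversity on amino-acid clonotype sets,
public/private and tissue-sharing classification, and the log2 cell-type
signature score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import Clonotype

logger = logging.getLogger(__name__)

#: Pairwise beta-diversity is only meaningful for reasonably sampled
#: repertoires; samples below this clonotype count are excluded.
MIN_CLONOTYPES_FOR_BETA = 10


def cpm(distinct_count: int, total_raw_reads: int) -> float:
    """Distinct clonotypes per one million raw RNA-Seq reads."""
    if total_raw_reads <= 0:
        raise ValueError("total_raw_reads must be positive")
    return distinct_count * 1e6 / total_raw_reads


def shannon_alpha(frequencies: Sequence[float]) -> float:
    """Shannon entropy of clonotype frequencies, in bits.

    Frequencies must sum to 1; zero frequencies contribute nothing. Base 2
    is used so that the entropy of n equifrequent clonotypes is log2(n).
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size and not math.isclose(float(freqs.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("frequencies must sum to 1")
    nz = freqs[freqs > 0]
    return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0


def sorensen_dice(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Sorensen-Dice similarity 2|A^B| / (|A| + |B|) of clonotype sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0
    return 2 * len(a & b) / (len(a) + len(b))


def classify_sharing(
    incidence: Mapping[str, Iterable[tuple[str, str]]]
) -> pd.DataFrame:
    """Label clonotypes by individual- and tissue-sharing.

    ``incidence`` maps each clonotype to its (individual, tissue)
    observations. A clonotype is public when seen in >= 2 individuals and
    multi-tissue when seen in >= 2 tissues. Returns one row per clonotype
    with the labels plus the observation counts.
    """
    rows = []
    for clonotype, obs in incidence.items():
        pairs = set(obs)
        individuals = {i for i, _ in pairs}
        tissues = {t for _, t in pairs}
        rows.append(
            {
                "clonotype": clonotype,
                "n_individuals": len(individuals),
                "n_tissues": len(tissues),
                "sharing": "public" if len(individuals) >= 2 else "private",
                "tissue_span": "multi_tissue" if len(tissues) >= 2 else "tissue_specific",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clonotype", "n_individuals", "n_tissues", "sharing", "tissue_span"],
    )


def sharing_crosstab(labels: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate (private, public) x (tissue_specific, multi_tissue)."""
    return pd.crosstab(labels["sharing"], labels["tissue_span"]).reindex(
        index=["private", "public"], columns=["tissue_specific", "multi_tissue"],
        fill_value=0,
    )


def signature_score(
    expression: Mapping[str, float], signature_genes: Sequence[str]
) -> float:
    """Cell-type signature score: mean log2 expression of signature genes.

    Signature genes missing from the expression map are excluded with a
    warning; values must be positive.
    """
    values = []
    for gene in signature_genes:
        if gene not in expression:
            logger.warning("signature gene %s missing from expression; excluded", gene)
            continue
        value = expression[gene]
        if value <= 0:
            raise ValueError(f"{gene}: expression must be positive for log2")
        values.append(math.log2(value))
    if not values:
        raise ValueError("no signature genes present in expression")
    return float(np.mean(values))


@dataclass
class RepertoireProfile:
    """Per-sample, per-chain repertoire summary."""

    sample_id: str
    chain: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    total_raw_reads: int = 0

    @property
    def distinct_count(self) -> int:
        return len(self.clonotypes)

    @property
    def cpm(self) -> float:
        return cpm(self.distinct_count, self.total_raw_reads)

    @property
    def alpha(self) -> float:
        freqs = [c.frequency for c in self.clonotypes]
        return shannon_alpha(freqs)

    @property
    def clonotype_set(self) -> set[str]:
        return {c.cdr3_aa for c in self.clonotypes}


def beta_diversity_matrix(
    profiles: Sequence[RepertoireProfile],
    min_clonotypes: int = MIN_CLONOTYPES_FOR_BETA,
) -> pd.DataFrame:
    """Pairwise Sorensen-Dice matrix over adequately sampled profiles."""
    usable = [p for p in profiles if p.distinct_count >= min_clonotypes]
    ids = [p.sample_id for p in usable]
    matrix = pd.DataFrame(np.eye(len(usable)), index=ids, columns=ids)
    for i, pa in enumerate(usable):
        for j in range(i + 1, len(usable)):
            d = sorensen_dice(pa.clonotype_set, usable[j].clonotype_set)
            matrix.iat[i, j] = matrix.iat[j, i] = d
    return matrix
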