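"""Geometric complement of the lncRNA-disease matrix via shared miRNAs.

The two auxiliary layers (lncRNA-miRNA and miRNA-disease) are combined
into a real-valued potential-association score

    LMD[i, j] = (LM[i, :] . MD[:, j]) / (||LM[i, :]||_1 + ||MD[:, j]||_1)

which counts the miRNAs shared by lncRNA i and disease j, normalised by
their total miRNA degrees.  The score is bounded by 0.5 (the dot product
never exceeds the smaller of the two L1 norms).  Merging with the
observed binary matrix by an elementwise maximum therefore never alters
an observed positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import BipartiteAdjacency, NetworkDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComplementedAssociation:
    """Real-valued potential (lmd) and merged (ld_new) association matrices."""

    lmd: np.ndarray
    ld_new: np.ndarray
    ld: BipartiteAdjacency
    lm: BipartiteAdjacency
    md: BipartiteAdjacency

    @property
    def shape(self) -> tuple[int, int]:
        return self.ld_new.shape


def geometric_complement(
    lm: BipartiteAdjacency, md: BipartiteAdjacency
) -> np.ndarray:
    """Two-hop lncRNA-disease evidence through shared miRNAs.

    Cells where the denominator is zero (the lncRNA has no miRNA
    partners and the disease has no miRNA partners) are defined as 0;
    their count is logged.
    """
    if lm.col_registry != md.row_registry:
        raise NetworkDataError(
            f"miRNA dimension mismatch: LM has {lm.shape[1]} columns, "
            f"MD has {md.shape[0]} rows"
        )
    num = lm.values.astype(float) @ md.values.astype(float)
    denom = lm.values.sum(axis=1, dtype=float)[:, None] + md.values.sum(
        axis=0, dtype=float
    )[None, :]
    zero_cells = int((denom == 0).sum())
    if zero_cells:
        logger.warning(
            "geometric complement: %d cell(s) with zero total miRNA degree set to 0",
            zero_cells,
        )
    return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)


def complement_merge(
    ld: BipartiteAdjacency,
    lmd: np.ndarray,
    lm: BipartiteAdjacency | None = None,
    md: BipartiteAdjacency | None = None,
) -> ComplementedAssociation:
    """Elementwise maximum of the observed LD matrix and the LMD score."""
    lmd = np.asarray(lmd, dtype=float)
    if lmd.shape != ld.shape:
        raise NetworkDataError(
            f"shape mismatch: LD is {ld.shape}, LMD is {lmd.shape}"
        )
    ld_new = np.maximum(ld.values.astype(float), lmd)
    return ComplementedAssociation(lmd=lmd, ld_new=ld_new, ld=ld, lm=lm, md=md)


def complement_pipeline(
    ld: BipartiteAdjacency, lm: BipartiteAdjacency, md: BipartiteAdjacency
) -> ComplementedAssociation:
    """Compute LMD from (LM, MD) and merge it with LD."""
    lmd = geometric_complement(lm, md)
    return complement_merge(ld, lmd, lm=lm, md=md)
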