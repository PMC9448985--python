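"""Jaccard and Gaussian interaction profile (GIP) similarities.

Both similarities are computed from the binary interaction profiles of an
entity in the lncRNA-disease matrix: rows for lncRNAs, columns for
diseases.  The GIP kernel is a Gaussian on profile distance whose
bandwidth is normalised by the mean squared profile norm, so a single
raw bandwidth parameter (lambda_tilde, default 1) transfers across
datasets of different density.  The two similarity matrices for one
entity kind are fused by the elementwise maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import BipartiteAdjacency, EntityRegistry, NetworkDataError

Axis = Literal["lncRNA-rows", "disease-columns"]


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityMatrix:
    """A square symmetric similarity matrix over one entity registry."""

    registry: EntityRegistry
    values: np.ndarray
    source: Literal["jaccard", "gip", "fused"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.registry)
        if v.shape != (n, n):
            raise SimilarityError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T):
            raise SimilarityError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise SimilarityError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _profiles(ld: BipartiteAdjacency, axis: Axis) -> tuple[np.ndarray, EntityRegistry]:
    if axis == "lncRNA-rows":
        return ld.values.astype(float), ld.row_registry
    if axis == "disease-columns":
        return ld.values.T.astype(float), ld.col_registry
    raise SimilarityError(f"unknown axis {axis!r}")


def jaccard_profiles(
    profiles: np.ndarray,
    denominator: Literal["union", "sum"] = "union",
) -> np.ndarray:
    """Pairwise Jaccard over the supports of a (n x p) profile matrix."""
    supp = (np.asarray(profiles) != 0).astype(float)
    inter = supp @ supp.T
    sizes = supp.sum(axis=1)
    if denominator == "union":
        denom = sizes[:, None] + sizes[None, :] - inter
    elif denominator == "sum":
        denom = sizes[:, None] + sizes[None, :]
    else:
        raise SimilarityError(f"unknown denominator mode {denominator!r}")
    sim = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    return (sim + sim.T) / 2.0  # exact symmetry against fp noise


def jaccard_similarity(
    ld: BipartiteAdjacency,
    axis: Axis,
    denominator: Literal["union", "sum"] = "union",
) -> SimilarityMatrix:
    """Jaccard similarity between binary interaction profiles.

    Entry (i, j) is |supp_i & supp_j| / |supp_i | supp_j|.  A pair of
    all-zero profiles has no evidence either way and is scored 0.  The
    ``sum`` denominator variant divides by |supp_i| + |supp_j| instead
    (a Dice-like coefficient) and is provided for comparison only.
    """
    if ld.values.size == 0:
        raise SimilarityError("empty adjacency matrix")
    profiles, registry = _profiles(ld, axis)
    return SimilarityMatrix(registry, jaccard_profiles(profiles, denominator), "jaccard")


def gip_profiles(profiles: np.ndarray, lambda_tilde: float = 1.0) -> np.ndarray:
    """Pairwise GIP kernel over a (n x p) profile matrix."""
    if lambda_tilde <= 0:
        raise SimilarityError("lambda_tilde must be positive")
    profiles = np.asarray(profiles, dtype=float)
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean() if sq_norms.size else 0.0
    if mean_sq == 0:
        raise SimilarityError(
            "undefined bandwidth: all interaction profiles are zero"
        )
    lam = lambda_tilde / mean_sq
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i.p_j
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(d2, 0.0, out=d2)
    sim = np.exp(-lam * d2)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def gip_similarity(
    ld: BipartiteAdjacency,
    axis: Axis,
    lambda_tilde: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity.

    Entry (i, j) = exp(-lambda * ||profile_i - profile_j||^2) with
    lambda = lambda_tilde / (mean squared profile norm).  The mean runs
    over all entities on the chosen axis, including those with empty
    profiles.
    """
    profiles, registry = _profiles(ld, axis)
    return SimilarityMatrix(registry, gip_profiles(profiles, lambda_tilde), "gip")


def fuse_max(a: SimilarityMatrix, b: SimilarityMatrix) -> SimilarityMatrix:
    """Fuse two similarity matrices by the elementwise maximum."""
    if a.registry != b.registry:
        raise SimilarityError("cannot fuse similarities over different registries")
    return SimilarityMatrix(a.registry, np.maximum(a.values, b.values), "fused")


def fused_similarity(
    ld: BipartiteAdjacency,
    axis: Axis,
    lambda_tilde: float = 1.0,
    denominator: Literal["union", "sum"] = "union",
) -> SimilarityMatrix:
    """Convenience: max-fusion of Jaccard and GIP over one axis."""
    return fuse_max(
        jaccard_similarity(ld, axis, denominator=denominator),
        gip_similarity(ld, axis, lambda_tilde=lambda_tilde),
    )
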