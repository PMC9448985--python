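"""Per-entity feature assembly and autoencoder compression.

Each lncRNA is described by its row of the complemented association
matrix (length d) followed by its row of the fused lncRNA similarity
matrix (length l); each disease by its column of the complemented matrix
(length l) followed by its column of the fused disease similarity
(length d).  Both raw widths equal l + d (652 at the reference scale of
240 lncRNAs and 412 diseases).  The raw tables are compressed entity-
kind by entity-kind with independently trained autoencoders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .autoencoder import Autoencoder, AutoencoderSpec
from .complement import ComplementedAssociation
from .network import EntityRegistry
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class FeatureTable:
    """A (n_entities x width) real feature matrix over one registry."""

    registry: EntityRegistry
    values: np.ndarray
    stage: Literal["raw", "encoded"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.registry):
            raise ValueError(
                f"expected ({len(self.registry)}, width) matrix, got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.values[self.registry.position(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.registry.names))


def build_raw_features(
    comp: ComplementedAssociation,
    lfj: SimilarityMatrix,
    dsj: SimilarityMatrix,
) -> tuple[FeatureTable, FeatureTable]:
    """Assemble raw lncRNA and disease feature tables.

    Column order is the complement block first, the similarity block
    second; both tables have width l + d.
    """
    l, d = comp.shape
    if lfj.shape != (l, l):
        raise ValueError(f"lncRNA similarity must be {l}x{l}, got {lfj.shape}")
    if dsj.shape != (d, d):
        raise ValueError(f"disease similarity must be {d}x{d}, got {dsj.shape}")
    lnc = np.hstack([comp.ld_new, lfj.values])
    dis = np.hstack([comp.ld_new.T, dsj.values.T])
    return (
        FeatureTable(comp.ld.row_registry, lnc, "raw"),
        FeatureTable(comp.ld.col_registry, dis, "raw"),
    )


def train_autoencoder(features: FeatureTable, spec: AutoencoderSpec) -> Autoencoder:
    """Train one autoencoder on a raw feature table."""
    if spec.input_dim != features.width:
        raise ValueError(
            f"spec input_dim {spec.input_dim} != feature width {features.width}"
        )
    return Autoencoder(spec).fit(features.values)


def encode(encoder: Autoencoder, features: FeatureTable) -> FeatureTable:
    """Project a raw feature table into the encoder's latent space."""
    return FeatureTable(features.registry, encoder.encode(features.values), "encoded")


def compress_features(
    features: FeatureTable,
    latent_dim: int = 256,
    seed: int = 0,
    epochs: int = 200,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
) -> tuple[FeatureTable, Autoencoder]:
    """Train an autoencoder on a raw table and return its encoding."""
    spec = AutoencoderSpec(
        input_dim=features.width,
        latent_dim=latent_dim,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        seed=seed,
    )
    ae = train_autoencoder(features, spec)
    return encode(ae, features), ae
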