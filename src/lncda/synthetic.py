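"""Synthetic tripartite lncRNA-miRNA-disease networks with planted structure.

The generator draws non-negative latent factors U (lncRNAs), V (miRNAs)
and W (diseases) from a gamma distribution and binarises the pairwise
factor products U W^T (LD), U V^T (LM) and V W^T (MD) by keeping the
top-scoring cells of each matrix at a target density.  Because the three
layers share the same factors, two-hop miRNA evidence is informative
about held-out lncRNA-disease pairs, which makes end-to-end recovery
testable without any external dataset.

A fraction of LD positives can be held out into a ground-truth list;
held-out pairs are removed from LD but remain scoreable candidates,
mirroring how novel associations are discovered in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import BipartiteAdjacency, EntityRegistry, write_adjacency

#: reference network dimensions: 240 lncRNAs, 495 miRNAs, 412 diseases,
#: with 2697 known lncRNA-disease associations.
DEFAULT_L, DEFAULT_M, DEFAULT_D = 240, 495, 412
DEFAULT_LD_DENSITY = 2697 / (240 * 412)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic tripartite network."""

    l: int = DEFAULT_L
    m: int = DEFAULT_M
    d: int = DEFAULT_D
    rank: int = 6
    ld_density: float = DEFAULT_LD_DENSITY
    lm_density: float = 0.01
    md_density: float = 0.05
    noise_flip_rate: float = 0.0
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dens in (
            ("ld_density", self.ld_density),
            ("lm_density", self.lm_density),
            ("md_density", self.md_density),
        ):
            if not 0 < dens < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {dens}")
        if not 1 <= self.rank <= min(self.l, self.m, self.d):
            raise ValueError(
                f"rank must lie in [1, min(l, m, d)], got {self.rank}"
            )
        if not 0 <= self.noise_flip_rate < 1:
            raise ValueError("noise_flip_rate must lie in [0, 1)")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in [0, 1)")


def _names(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(n))


def _binarize_top(scores: np.ndarray, density: float, rng: np.random.Generator) -> np.ndarray:
    """Keep the top round(density * size) cells; random tie-breaks."""
    n_ones = int(round(density * scores.size))
    flat = scores.ravel() + rng.uniform(0, 1e-9, scores.size)  # break exact ties
    idx = np.argpartition(flat, -n_ones)[-n_ones:] if n_ones else np.empty(0, int)
    out = np.zeros(scores.size, dtype=np.int8)
    out[idx] = 1
    return out.reshape(scores.shape)


def _flip(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return mat
    n_flip = int(round(rate * mat.size))
    idx = rng.choice(mat.size, size=n_flip, replace=False)
    flat = mat.ravel().copy()
    flat[idx] = 1 - flat[idx]
    return flat.reshape(mat.shape)


def generate_network(
    cfg: SyntheticConfig,
) -> tuple[BipartiteAdjacency, BipartiteAdjacency, BipartiteAdjacency, list[tuple[int, int]]]:
    """Generate (LD, MD, LM, truth) with planted shared low-rank structure.

    ``truth`` lists (lncRNA index, disease index) positives removed from
    LD; with holdout_fraction=0 it is empty.
    """
    rng = np.random.default_rng(cfg.seed)
    u = rng.gamma(2.0, 1.0, size=(cfg.l, cfg.rank))
    v = rng.gamma(2.0, 1.0, size=(cfg.m, cfg.rank))
    w = rng.gamma(2.0, 1.0, size=(cfg.d, cfg.rank))
    ld = _flip(_binarize_top(u @ w.T, cfg.ld_density, rng), cfg.noise_flip_rate, rng)
    lm = _flip(_binarize_top(u @ v.T, cfg.lm_density, rng), cfg.noise_flip_rate, rng)
    md = _flip(_binarize_top(v @ w.T, cfg.md_density, rng), cfg.noise_flip_rate, rng)

    ones = np.argwhere(ld == 1)
    n_hold = int(round(cfg.holdout_fraction * len(ones)))
    truth: list[tuple[int, int]] = []
    if n_hold:
        held = ones[rng.choice(len(ones), size=n_hold, replace=False)]
        ld[held[:, 0], held[:, 1]] = 0
        truth = sorted((int(i), int(j)) for i, j in held)

    lnc_reg = EntityRegistry("lncRNA", _names("L", cfg.l))
    mir_reg = EntityRegistry("miRNA", _names("M", cfg.m))
    dis_reg = EntityRegistry("disease", _names("D", cfg.d))
    return (
        BipartiteAdjacency(lnc_reg, dis_reg, ld),
        BipartiteAdjacency(mir_reg, dis_reg, md),
        BipartiteAdjacency(lnc_reg, mir_reg, lm),
        truth,
    )


def make_fixture_suite(outdir: str | Path) -> Path:
    """Write the small hand-computable fixtures plus a 12x10x8 planted net.

    Regeneration is byte-identical (fixed seeds, fixed float formats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _write_dense(name: str, rows: list[str], cols: list[str], mat) -> None:
        lines = ["," + ",".join(cols)]
        for rname, row in zip(rows, mat):
            cells = [
                str(int(x)) if float(x) == int(x) else f"{float(x):.12f}"
                for x in row
            ]
            lines.append(rname + "," + ",".join(cells))
        (outdir / name).write_text("\n".join(lines) + "\n")

    # Jaccard/GIP worked example: rows [1,0,1] and [1,1,0].
    _write_dense("jaccard_rows_ld.csv", ["L1", "L2"], ["D1", "D2", "D3"], [[1, 0, 1], [1, 1, 0]])
    _write_dense("jaccard_rows_expected.csv", ["L1", "L2"], ["L1", "L2"],
                 [[1.0, 1 / 3], [1 / 3, 1.0]])
    e1 = float(np.exp(-1.0))
    _write_dense("gip_rows_expected.csv", ["L1", "L2"], ["L1", "L2"], [[1.0, e1], [e1, 1.0]])

    # Geometric-complement worked example.
    _write_dense("lmd_2x2_lm.csv", ["L1", "L2"], ["M1", "M2"], [[1, 1], [0, 1]])
    _write_dense("lmd_2x2_md.csv", ["M1", "M2"], ["D1", "D2"], [[1, 0], [1, 1]])
    _write_dense("lmd_2x2_expected.csv", ["L1", "L2"], ["D1", "D2"],
                 [[0.5, 1 / 3], [1 / 3, 0.5]])
    _write_dense("lmd_2x2_ld.csv", ["L1", "L2"], ["D1", "D2"], [[1, 0], [0, 0]])
    _write_dense("ldnew_2x2_expected.csv", ["L1", "L2"], ["D1", "D2"],
                 [[1.0, 1 / 3], [1 / 3, 0.5]])

    # A small planted network for end-to-end smoke tests.
    cfg = SyntheticConfig(
        l=12, m=10, d=8, rank=3,
        ld_density=0.25, lm_density=0.25, md_density=0.25,
        holdout_fraction=0.1, seed=12345,
    )
    ld, md, lm, truth = generate_network(cfg)
    write_adjacency(ld, outdir / "planted_12x10x8_ld.csv")
    write_adjacency(md, outdir / "planted_12x10x8_md.csv")
    write_adjacency(lm, outdir / "planted_12x10x8_lm.csv")
    lines = ["lncRNA\tdisease"]
    lines += [
        f"{ld.row_registry.names[i]}\t{ld.col_registry.names[j]}" for i, j in truth
    ]
    (outdir / "planted_12x10x8_truth.tsv").write_text("\n".join(lines) + "\n")
    return outdir
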