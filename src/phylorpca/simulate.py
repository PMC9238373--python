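"""Three-block microbiome simulator with a block-synchronized phylogeny.

The generator emulates a community with three environment blocks of
features: feature ``i`` carries a location parameter mu_i, each sample's
block a location g_j, and the pre-closure intensity follows a Gaussian
kernel exp(-(mu_i - g_j)^2 / (2 sigma^2)) / sqrt(2 pi sigma^2), so features
are most abundant in samples of their own block, with a configurable subset
shared between blocks.  After additive noise and closure to proportions,
counts are drawn Poisson-lognormally: y_ij ~ Poisson(n p_ij exp(eps)) with
eps ~ Normal(0, phi^2), which reproduces the overdispersion of real
sequencing depth.  The companion phylogeny is a caterpillar-of-clades whose
postorder tip sequence matches the block order, and can be desynchronized
by graded tip-label shuffling or replaced by a signal-free random tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .phylo import Phylogeny, random_tree, shuffle_tips

logger = logging.getLogger("phylorpca")

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "block_proportions",
    "pln_sample",
    "sorted_block_tree",
    "simulate",
]


@dataclass
class SimulationConfig:
    """Parameters of the block simulation.

    sigma is the Gaussian block spread; block_centers are the shared
    feature/sample location parameters (one per block); overlap_fraction of
    each block's features is placed between blocks; noise_sd scales both
    the additive Gaussian and the additive uniform noise on the pre-closure
    intensities; depth is the expected reads/sample and phi the lognormal
    overdispersion of the Poisson intensity.
    """

    n_blocks: int = 3
    features_per_block: int = 100
    samples_per_block: int = 20
    sigma: float = 1.0
    block_centers: tuple[float, ...] = (0.0, 5.0, 10.0)
    overlap_fraction: float = 0.1
    noise_sd: float = 0.01
    depth: int = 2_000_000
    phi: float = 0.5
    shuffle_proportion: float = 0.0
    use_random_tree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if not 0 <= self.shuffle_proportion <= 1:
            raise ValueError("shuffle_proportion must be in [0, 1]")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_blocks < 1 or self.features_per_block < 1 or self.samples_per_block < 1:
            raise ValueError("block counts must be >= 1")
        if len(self.block_centers) != self.n_blocks:
            raise ValueError("need one block center per block")


@dataclass
class SimulatedDataset:
    """Counts, labels, tree and ground truth emitted by :func:`simulate`."""

    counts: pd.DataFrame  # samples x features
    sample_labels: pd.Series  # sample -> block name
    tree: Phylogeny
    feature_blocks: pd.Series  # feature -> block name (home block)
    proportions: pd.DataFrame  # the closed p matrix behind the counts
    config: SimulationConfig


def _feature_centers(cfg: SimulationConfig) -> tuple[np.ndarray, list[str], pd.Series]:
    """Per-feature mu_i, feature ids (block-ordered) and home-block labels.

    The first ``round(overlap_fraction * features_per_block)`` features of
    each block are 'shared': their mu sits midway between the block's
    center and the next block's (the last block shares toward the mean of
    all centers), emulating taxa found across environments.
    """
    centers = np.asarray(cfg.block_centers, dtype=float)
    n_shared = int(round(cfg.overlap_fraction * cfg.features_per_block))
    mus, ids, blocks = [], [], []
    for b in range(cfg.n_blocks):
        if b + 1 < cfg.n_blocks:
            shared_mu = 0.5 * (centers[b] + centers[b + 1])
        else:
            shared_mu = float(centers.mean())
        for f in range(cfg.features_per_block):
            ids.append(f"B{b}F{f:03d}")
            blocks.append(f"block{b}")
            mus.append(shared_mu if f < n_shared else centers[b])
    return np.asarray(mus), ids, pd.Series(blocks, index=ids, name="block")


def block_proportions(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Closed per-sample proportion matrix of the block model.

    Gaussian-kernel intensities (negative exponent) are perturbed with
    additive Normal(0, noise_sd) and Uniform(0, noise_sd) noise, clipped at
    zero, and closed per sample.  Returns ``(p, sample_labels,
    feature_blocks)`` with samples as rows.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mus, feature_ids, feature_blocks = _feature_centers(cfg)
    centers = np.asarray(cfg.block_centers, dtype=float)
    sample_ids, sample_labels, gs = [], [], []
    for b in range(cfg.n_blocks):
        for s in range(cfg.samples_per_block):
            sample_ids.append(f"S{b * cfg.samples_per_block + s:03d}")
            sample_labels.append(f"block{b}")
            gs.append(centers[b])
    g = np.asarray(gs)

    norm = 1.0 / np.sqrt(2.0 * np.pi * cfg.sigma**2)
    intensity = norm * np.exp(-((mus[None, :] - g[:, None]) ** 2) / (2.0 * cfg.sigma**2))
    intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=intensity.shape)
    intensity = intensity + rng.uniform(0.0, cfg.noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    totals = intensity.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("degenerate config: a sample lost all intensity to noise")
    p = pd.DataFrame(intensity / totals[:, None], index=sample_ids, columns=feature_ids)
    return p, pd.Series(sample_labels, index=sample_ids, name="block"), feature_blocks


def pln_sample(
    p: pd.DataFrame, depth: int, phi: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Poisson-lognormal counts from a row-closed proportion matrix.

    y_ij ~ Poisson(depth * p_ij * exp(eps_ij)), eps_ij ~ Normal(0, phi^2).
    The expected per-sample total is depth * exp(phi^2 / 2) (lognormal mean
    inflation); phi = 0 recovers pure Poisson resampling at ``depth``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = depth * p.to_numpy(dtype=float)
    if phi > 0:
        lam = lam * np.exp(rng.normal(0.0, phi, size=lam.shape))
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=p.index, columns=p.columns)


def _caterpillar(names: list[str]) -> TreeNode:
    """Ladder tree whose postorder tip sequence equals ``names``."""
    node = TreeNode(name=names[0], length=1.0)
    for name in names[1:]:
        tip = TreeNode(name=name, length=1.0)
        node = TreeNode(children=[node, tip], length=1.0)
    return node


def sorted_block_tree(
    feature_ids_by_block: list[list[str]], seed: int = 0
) -> Phylogeny:
    """Caterpillar-of-clades tree whose postorder tips follow block order.

    Each block becomes a ladder clade of its features (in order); clades are
    chained so the full postorder tip sequence is block 0's tips, then
    block 1's, and so on.  All branch lengths are 1.
    """
    all_ids = [f for block in feature_ids_by_block for f in block]
    if not all_ids:
        raise ValueError("no features")
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("overlapping feature ids between blocks")
    clades = [_caterpillar(list(block)) for block in feature_ids_by_block if block]
    root = clades[0]
    for clade in clades[1:]:
        root = TreeNode(children=[root, clade], length=1.0)
    root.length = None
    return Phylogeny(root)


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full pipeline: proportions -> PLN counts -> (shuffled) tree."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    child = lambda ss: int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
    p, sample_labels, feature_blocks = block_proportions(
        cfg, np.random.default_rng(seeds[0])
    )
    counts = pln_sample(p, cfg.depth, cfg.phi, np.random.default_rng(seeds[1]))
    blocks = [
        list(feature_blocks.index[feature_blocks == f"block{b}"])
        for b in range(cfg.n_blocks)
    ]
    if cfg.use_random_tree:
        tree = random_tree(list(p.columns), seed=child(seeds[2]))
    else:
        tree = sorted_block_tree(blocks, seed=child(seeds[2]))
        if cfg.shuffle_proportion > 0:
            tree = shuffle_tips(tree, cfg.shuffle_proportion, seed=child(seeds[2]))
    return SimulatedDataset(counts, sample_labels, tree, feature_blocks, p, cfg)
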