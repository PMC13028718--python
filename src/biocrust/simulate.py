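"""Synthetic community generators with known ground truth.

Each generator emits data with exactly the statistical structure one
analysis stage assumes, so the whole pipeline can be exercised and
validated without sequencing data:

* :func:`simulate_neutral` — the stationary Sloan sampling scheme: a
  lognormal (or log-series) metacommunity, per-sample composition drawn
  Dirichlet(Nm * p) and reads multinomial at fixed depth. The Dirichlet
  concentration IS the Nm the neutral-model fitter estimates, so round-trip
  recovery is a meaningful consistency check.
* :func:`simulate_niche` — deterministic environmental filtering: each ASV
  carries a Gaussian response to a per-sample environmental value, scaled by
  a selection-strength knob; strength 0 degenerates to neutral sampling at
  infinite Nm.
* :func:`simulate_blocks` — planted covariance blocks for the network stage:
  per-sample latent factors, signed loadings per block, log-linear abundance
  model, multinomial reads.
* :func:`simulate_growth_chain` — the linear causal chain
  inoculation -> community axis -> latent growth, with organic matter and
  coverage as two noisy manifest indicators of growth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = [
    "SimulationConfig",
    "BlockSpec",
    "simulate_neutral",
    "simulate_niche",
    "simulate_blocks",
    "simulate_growth_chain",
    "metacommunity_abundances",
]


@dataclass
class BlockSpec:
    """One planted block: `size` ASVs loading on latent `latent_id` with
    `sign` (+1/-1) and loading magnitude `strength`. Blocks sharing a latent
    with opposite signs are anti-correlated across blocks."""

    size: int
    sign: int = 1
    latent_id: int = 0
    strength: float = 2.0


@dataclass
class SimulationConfig:
    """Shared knobs for the generators. Defaults mirror the study design:
    30 samples (6 treatment groups x 5 replicates scale), rarefaction depth
    20,000 reads, lognormal metacommunity with sigma = 1.5 for realistic
    rank-abundance skew."""

    n_samples: int = 30
    n_asvs: int = 500
    depth: int = 20000
    metacommunity: str = "lognormal"  # or "logseries"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    logseries_alpha: float = 0.99
    Nm: float = 2000.0
    niche_strength: float = 5.0
    niche_width: float = 0.3
    blocks: list[BlockSpec] = field(default_factory=list)
    # total metacommunity share of all block members combined; None keeps the
    # raw draw. A small share emulates a rare planted guild, which keeps the
    # compositional denominator stable so background taxa stay uncorrelated.
    block_share: float | None = None
    chain: tuple[float, float] = (0.59, 0.64)
    noise_sd: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chain"] = list(self.chain)
        return d


def metacommunity_abundances(config: SimulationConfig, rng: np.random.Generator):
    """Relative abundances of the source pool under the configured model."""
    if config.metacommunity == "lognormal":
        raw = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, config.n_asvs)
    elif config.metacommunity == "logseries":
        raw = rng.logseries(config.logseries_alpha, config.n_asvs).astype(float)
    else:
        raise ValueError(f"unknown metacommunity model {config.metacommunity!r}")
    return raw / raw.sum()


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _table(counts: np.ndarray, prefix: str = "sample") -> AbundanceTable:
    n, m = counts.shape
    return AbundanceTable(_ids(prefix, n), _ids("ASV_", m), counts)


def _dirichlet(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw via gamma variates; tolerates very small alphas
    (underflow to exact zero just means the taxon is absent locally)."""
    g = rng.gamma(np.maximum(alpha, 1e-300))
    total = g.sum()
    if total <= 0:  # pathological: retry with a flat floor
        g = rng.gamma(np.maximum(alpha, 1e-3))
        total = g.sum()
    return g / total


def simulate_neutral(config: SimulationConfig) -> AbundanceTable:
    """Neutral local communities: Dirichlet(Nm * p) composition, multinomial
    reads at `depth`. Fitted Nm is a consistent estimator of config.Nm."""
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    if config.Nm <= 0:
        raise ValueError("Nm must be positive")
    rng = np.random.default_rng(config.seed)
    p = metacommunity_abundances(config, rng)
    alpha = config.Nm * p
    counts = np.empty((config.n_samples, config.n_asvs), dtype=np.int64)
    for i in range(config.n_samples):
        local = _dirichlet(alpha, rng)
        counts[i] = rng.multinomial(config.depth, local)
    return _table(counts)


def simulate_niche(config: SimulationConfig) -> AbundanceTable:
    """Environmentally filtered communities.

    Samples sit on an environmental gradient in [0, 1]; each ASV has an
    optimum and Gaussian response of width `niche_width`. Expected local
    abundance is the metacommunity abundance modulated by
    response^strength, renormalised; reads multinomial. strength = 0 gives
    pure multinomial sampling of the metacommunity (the infinite-Nm neutral
    limit)."""
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    if config.niche_strength < 0:
        raise ValueError("niche strength must be >= 0")
    rng = np.random.default_rng(config.seed)
    p = metacommunity_abundances(config, rng)
    env = rng.uniform(0, 1, config.n_samples)
    optima = rng.uniform(0, 1, config.n_asvs)
    counts = np.empty((config.n_samples, config.n_asvs), dtype=np.int64)
    for i in range(config.n_samples):
        response = np.exp(
            -((env[i] - optima) ** 2) / (2 * config.niche_width**2)
        )
        w = p * response**config.niche_strength
        total = w.sum()
        if total <= 0:
            w = p.copy()
            total = w.sum()
        counts[i] = rng.multinomial(config.depth, w / total)
    return _table(counts)


def simulate_blocks(config: SimulationConfig) -> AbundanceTable:
    """Planted-block communities for the co-occurrence network stage.

    Per sample, each latent factor is standard normal; an ASV in a block
    gets log-abundance = log(metacommunity p) + sign * strength * latent +
    noise, softmax across ASVs, then multinomial reads. ASVs in the same
    block co-vary positively; blocks sharing a latent with opposite signs
    co-vary negatively."""
    if not config.blocks:
        raise ValueError("network_blocks must be non-empty")
    total_block = sum(b.size for b in config.blocks)
    if total_block > config.n_asvs:
        raise ValueError("block sizes exceed n_asvs")
    rng = np.random.default_rng(config.seed)
    p = metacommunity_abundances(config, rng)
    if config.block_share is not None:
        if not (0 < config.block_share < 1):
            raise ValueError("block_share must lie in (0, 1)")
        if total_block >= config.n_asvs:
            raise ValueError("block_share needs background ASVs outside the blocks")
        in_block = np.zeros(config.n_asvs, dtype=bool)
        in_block[:total_block] = True
        p[in_block] *= config.block_share / p[in_block].sum()
        p[~in_block] *= (1 - config.block_share) / p[~in_block].sum()
    n_latents = max(b.latent_id for b in config.blocks) + 1

    loadings = np.zeros((config.n_asvs, n_latents))
    start = 0
    for b in config.blocks:
        loadings[start : start + b.size, b.latent_id] = b.sign * b.strength
        start += b.size

    counts = np.empty((config.n_samples, config.n_asvs), dtype=np.int64)
    for i in range(config.n_samples):
        latent = rng.normal(size=n_latents)
        log_w = (
            np.log(p)
            + loadings @ latent
            + config.noise_sd * rng.normal(size=config.n_asvs)
        )
        w = np.exp(log_w - log_w.max())
        counts[i] = rng.multinomial(config.depth, w / w.sum())
    return _table(counts)


def simulate_growth_chain(config: SimulationConfig) -> pd.DataFrame:
    """Linear causal chain inoculation -> community axis -> growth.

    X is a balanced binary inoculation indicator; M = b1*X + e with e scaled
    so M is standardized in expectation; latent growth Y = b2*M + e likewise;
    organic matter (OM) and coverage are Y plus independent noise of sd
    `noise_sd` — two manifest indicators for the PCA composite step.

    Returns a DataFrame with columns inoculation, community_axis, OM,
    coverage and (for oracle tests) latent_growth.
    """
    b1, b2 = config.chain
    if not (-1 < b1 < 1 and -1 < b2 < 1):
        raise ValueError("chain coefficients must lie in (-1, 1)")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    x = np.tile([0.0, 1.0], (n + 1) // 2)[:n]
    rng.shuffle(x)
    xz = (x - x.mean()) / x.std() if x.std() > 0 else x
    m = b1 * xz + np.sqrt(1 - b1**2) * rng.normal(size=n)
    y = b2 * m + np.sqrt(1 - b2**2) * rng.normal(size=n)
    om = y + config.noise_sd * rng.normal(size=n)
    coverage = y + config.noise_sd * rng.normal(size=n)
    return pd.DataFrame(
        {
            "inoculation": x,
            "community_axis": m,
            "OM": om,
            "coverage": coverage,
            "latent_growth": y,
        },
        index=_ids("sample", n),
    )
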