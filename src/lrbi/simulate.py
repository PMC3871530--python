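"""Random network and dataset generation for benchmarking the estimator.

Networks are directed Erdős–Rényi-style graphs: each admissible ordered pair
(i, j), i != j, carries an edge independently with probability ``Ne/(m-1)``
(``Ne`` = average out-edges per gene). In acyclic mode a random topological
order is drawn first and only order-respecting pairs are admissible, so the
adjacency matrix is strictly triangular under that order. Nonzero weights
have magnitude Uniform(weight_low, weight_high) with a random sign; the eQTL
effect matrix is the identity. Genotypes are i.i.d. over {0, 1, 2} with
probabilities (0.25, 0.5, 0.25) — the F2-cross coding — and expression is
produced by the forward structural solve with Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Dataset, GRNModel, NoiseSpec, generate_expression

__all__ = ["SimConfig", "sample_network", "sample_genotypes", "simulate"]

_MAX_RESAMPLES = 100
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Parameters
    ----------
    m : gene count.
    N : sample (individual) count.
    Ne : average number of out-edges per gene; edge probability is Ne/(m-1)
        per admissible ordered pair.
    cyclic : allow feedback loops (all ordered pairs admissible) instead of
        drawing a topological order first.
    sigma2 : measurement-noise variance.
    weight_low, weight_high : magnitude bounds of nonzero regulatory effects.
    genotype_probs : probabilities of the three genotype codes.
    genotype_codes : the code set itself; {0,1,2} by default, {1,2,3} also
        supported.
    edge_rate_basis : "per_pair" (default) keeps probability Ne/(m-1) per
        admissible pair; "per_gene" rescales so the expected total edge count
        is m*Ne regardless of admissibility (differs only in acyclic mode).
    seed : root seed; network, genotypes and noise get independent substreams.
    """

    m: int
    N: int
    Ne: float = 3.0
    cyclic: bool = False
    sigma2: float = 0.01
    weight_low: float = 0.5
    weight_high: float = 1.0
    genotype_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    genotype_codes: tuple[int, int, int] = (0, 1, 2)
    edge_rate_basis: str = "per_pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.Ne <= self.m - 1:
            raise ValueError(f"Ne must lie in (0, m-1], got {self.Ne}")
        if not 0 < self.weight_low < self.weight_high:
            raise ValueError("need 0 < weight_low < weight_high")
        if not np.isclose(sum(self.genotype_probs), 1.0):
            raise ValueError("genotype_probs must sum to 1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.edge_rate_basis not in ("per_pair", "per_gene"):
            raise ValueError("edge_rate_basis must be 'per_pair' or 'per_gene'")
        if len(self.genotype_codes) != len(self.genotype_probs):
            raise ValueError("one probability per genotype code required")

    def _seedseq(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed)


def _edge_probability(config: SimConfig, n_admissible: int) -> float:
    if config.edge_rate_basis == "per_pair":
        return config.Ne / (config.m - 1)
    # per_gene: expected total of m*Ne edges spread over the admissible pairs
    return min(1.0, config.m * config.Ne / n_admissible)


def sample_network(
    config: SimConfig,
    seed: np.random.SeedSequence | None = None,
) -> GRNModel:
    """Draw a random network consistent with ``config``.

    Cyclic networks are resampled (up to 100 times) until ``I - B`` is well
    conditioned, so the forward structural solve is stable. Deterministic
    given the seed.
    """
    if seed is None:
        seed = config._seedseq().spawn(3)[0]
    rng = np.random.default_rng(seed)
    m = config.m
    for _ in range(_MAX_RESAMPLES):
        if config.cyclic:
            admissible = ~np.eye(m, dtype=bool)
        else:
            order = rng.permutation(m)
            # gene order[a] may regulate gene order[b] only if a < b:
            # edges respect the drawn topological order
            rank = np.empty(m, dtype=int)
            rank[order] = np.arange(m)
            # admissible[target, regulator]: regulator earlier in the order
            admissible = rank[None, :] < rank[:, None]
        p = _edge_probability(config, int(admissible.sum()))
        present = admissible & (rng.random((m, m)) < p)
        magnitude = rng.uniform(config.weight_low, config.weight_high, size=(m, m))
        sign = rng.choice([-1.0, 1.0], size=(m, m))
        B = np.where(present, sign * magnitude, 0.0)
        if not config.cyclic:
            return GRNModel(B=B, F=np.eye(m))
        if np.linalg.cond(np.eye(m) - B) < _COND_LIMIT:
            return GRNModel(B=B, F=np.eye(m))
    raise RuntimeError(
        f"could not sample a stable cyclic network in {_MAX_RESAMPLES} attempts"
    )


def sample_genotypes(
    config: SimConfig,
    seed: np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Draw the m x N genotype matrix, entries i.i.d. over the code set."""
    if seed is None:
        seed = config._seedseq().spawn(3)[1]
    rng = np.random.default_rng(seed)
    return rng.choice(
        np.asarray(config.genotype_codes),
        size=(config.m, config.N),
        p=np.asarray(config.genotype_probs, dtype=float),
    )


def simulate(config: SimConfig) -> tuple[GRNModel, Dataset]:
    """Draw a network, genotypes and noisy expression; return truth and data.

    The root seed is split into independent substreams for the network, the
    genotypes and the noise, so each component is individually reproducible.
    """
    net_seed, geno_seed, noise_seed = config._seedseq().spawn(3)
    model = sample_network(config, seed=net_seed)
    X = sample_genotypes(config, seed=geno_seed)
    dataset = generate_expression(
        model,
        X,
        NoiseSpec(config.sigma2),
        seed=noise_seed,
        genotype_codes=config.genotype_codes,
    )
    return model, dataset


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different root seed (replicate helper)."""
    return replace(config, seed=seed)
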