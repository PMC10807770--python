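"""Poisson null and power simulations for score calibration checks.

The null design draws an n_samples x n_genes matrix of i.i.d. Poisson(lambda)
counts, applies library-size normalization, and scores a single gene set
containing the first ``set_size`` genes with the per-gene mean as the
reference profile and neutral tissue weights (t* = 1). The type I error is
the fraction of sample-level p-values below alpha. The power design adds a
constant offset lambda * delta to the first ``n_affected_samples`` samples
and first ``set_size`` genes of the counts before normalization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .core import TpacConfig, tpac
from .gene_sets import GeneSetCollection

__all__ = [
    "NullSimConfig",
    "PowerSimConfig",
    "SimulationResult",
    "simulate_null_counts",
    "normalize_library_size",
    "add_offset",
    "estimate_type1_error",
    "estimate_power",
]

DEFAULT_DELTA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 21))


@dataclass(frozen=True)
class NullSimConfig:
    n_samples: int = 10_000
    n_genes: int = 100
    lam: float = 5.0
    set_size: int = 20
    alpha: float = 0.05
    seed: int = 0
    n_permutations: int = 1

    def __post_init__(self) -> None:
        if self.set_size > self.n_genes:
            raise ValueError("set_size cannot exceed n_genes")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class PowerSimConfig(NullSimConfig):
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID
    n_affected_samples: int = 1_000
    # Reuse one base count matrix (and permutation stream) across the delta
    # grid. Common random numbers keep the power curve monotone in delta
    # instead of burying the trend in per-point Monte Carlo noise.
    share_noise: bool = True

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_affected_samples > self.n_samples:
            raise ValueError("n_affected_samples cannot exceed n_samples")
        if any(d <= 0 for d in self.delta_grid):
            raise ValueError("all deltas must be positive")


@dataclass
class SimulationResult:
    """Rejection rates per condition ('null' or a delta value), with the
    per-condition denominator and the config echo."""

    rates: dict
    n_tested: dict
    seed: int
    config: dict = field(default_factory=dict)


def simulate_null_counts(config: NullSimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """i.i.d. Poisson(lambda) count matrix, deterministic given the seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return rng.poisson(config.lam, size=(config.n_samples, config.n_genes))


def normalize_library_size(counts) -> np.ndarray:
    """Depth-matching normalization: scale each sample so its total equals
    the mean total across samples, preserving within-sample proportions."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("sample with zero total count cannot be normalized")
    return counts * (totals.mean() / totals)[:, np.newaxis]


def add_offset(counts, delta: float, n_affected_samples: int, set_size: int, lam: float) -> np.ndarray:
    """Add a constant offset lambda * delta to the leading block of samples
    and genes (applied to raw counts, before normalization)."""
    counts = np.asarray(counts, dtype=float).copy()
    counts[:n_affected_samples, :set_size] += lam * delta
    return counts


def _score_pvalues(normalized: np.ndarray, config: NullSimConfig, perm_seed: int) -> np.ndarray:
    """Run the scoring pipeline on a normalized simulation matrix.

    The reference t is the per-gene mean of the scored matrix and t_bar = t,
    so tissue weighting is neutral (t* = 1); one gene set covers the first
    ``set_size`` genes. Returns the sample-level p-values from S.
    """
    n, p = normalized.shape
    gene_ids = [f"g{j}" for j in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    t = normalized.mean(axis=0)
    collection = GeneSetCollection(sets={"SIM_SET": gene_ids[: config.set_size]})
    result = tpac(
        normalized,
        sample_ids,
        gene_ids,
        t,
        t.copy(),
        collection,
        TpacConfig(
            seed=perm_seed,
            n_permutations=config.n_permutations,
            min_set_size=min(config.set_size, 5),
        ),
    )
    return result.P[:, 0]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def estimate_type1_error(config: NullSimConfig = NullSimConfig()) -> SimulationResult:
    """Empirical type I error of sample-level p-values under the null design."""
    count_seed, perm_seed = _spawn_seeds(config.seed, 2)
    counts = simulate_null_counts(config, rng=np.random.default_rng(count_seed))
    normalized = normalize_library_size(counts)
    pvalues = _score_pvalues(normalized, config, perm_seed)
    rate = float(np.mean(pvalues < config.alpha))
    return SimulationResult(
        rates={"null": rate},
        n_tested={"null": int(pvalues.size)},
        seed=config.seed,
        config=asdict(config),
    )


def estimate_power(config: PowerSimConfig = PowerSimConfig()) -> SimulationResult:
    """Empirical power over the delta grid.

    For each delta the offset is added to a Poisson count matrix, which is
    then normalized and scored; power is the fraction of affected samples
    with p < alpha. With ``share_noise`` (default) one base count matrix and
    one permutation stream serve the whole grid; otherwise every delta gets
    an independent simulation.
    """
    seeds = _spawn_seeds(config.seed, 2 * len(config.delta_grid))
    rates: dict = {}
    n_tested: dict = {}
    base = simulate_null_counts(config, rng=np.random.default_rng(seeds[0]))
    for i, delta in enumerate(config.delta_grid):
        if config.share_noise:
            counts, perm_seed = base, seeds[1]
        else:
            counts = simulate_null_counts(config, rng=np.random.default_rng(seeds[2 * i]))
            perm_seed = seeds[2 * i + 1]
        shifted = add_offset(
            counts, delta, config.n_affected_samples, config.set_size, config.lam
        )
        normalized = normalize_library_size(shifted)
        pvalues = _score_pvalues(normalized, config, perm_seed)
        affected = pvalues[: config.n_affected_samples]
        rates[delta] = float(np.mean(affected < config.alpha))
        n_tested[delta] = int(affected.size)
    return SimulationResult(rates=rates, n_tested=n_tested, seed=config.seed, config=asdict(config))
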