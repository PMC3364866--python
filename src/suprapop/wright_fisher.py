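"""Forward-time Wright-Fisher simulation and an exact Markov-chain oracle.

The neutral Wright-Fisher model: a diploid population of N individuals
carries 2N allele copies; each generation the allele count is a binomial
draw Binomial(2N, p) from the current frequency p, until the allele is
lost (count 0) or fixed (count 2N). :func:`simulate_absorption` estimates
absorption times by Monte-Carlo over many replicate loci;
:func:`markov_absorption_oracle` computes the same quantities exactly from
the (2N+1)-state transition matrix (feasible for 2N up to a few hundred),
so the simulator and the closed-form diffusion prediction
t(p) = -4N[(1-p)ln(1-p) + p ln p] can be validated against each other.

:func:`simulate_divergence_with_geneflow` runs two populations that
diverge from a common ancestral frequency while exchanging gametes at a
symmetric per-generation rate m (island-model gene flow standing in for
interspecific hybridisation), tracking how many loci remain polymorphic in
each and jointly in both — the simulated analogue of shared polymorphism
between hybridising species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WFConfig",
    "AbsorptionStats",
    "GeneFlowConfig",
    "SharedPolyStats",
    "simulate_absorption",
    "markov_absorption_oracle",
    "segregating_fraction",
    "simulate_divergence_with_geneflow",
]


@dataclass(frozen=True)
class WFConfig:
    """Single-population simulation settings.

    ``max_generations`` defaults to 40N, long enough that essentially all
    replicates absorb (mean absorption is < 2.8N generations).
    """

    diploid_size: int
    initial_frequency: float
    replicates: int = 10_000
    max_generations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diploid_size < 1:
            raise ValueError("diploid_size must be >= 1")
        if not 0.0 <= self.initial_frequency <= 1.0:
            raise ValueError("initial_frequency must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_generations is not None and self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def horizon(self) -> int:
        return self.max_generations or 40 * self.diploid_size


@dataclass(frozen=True)
class AbsorptionStats:
    """Monte-Carlo absorption summary.

    ``mean_absorption_time`` averages over absorbed replicates only;
    replicates still segregating at the horizon are reported separately in
    ``unabsorbed_fraction``, never silently counted as absorbed.
    """

    mean_absorption_time: float
    standard_error: float
    fixation_fraction: float
    loss_fraction: float
    unabsorbed_fraction: float
    segregating_fraction_at: dict[int, float]
    n_replicates: int


def simulate_absorption(
    config: WFConfig, checkpoints: tuple[int, ...] = ()
) -> AbsorptionStats:
    """Simulate neutral drift to absorption for many replicate loci.

    All replicates are advanced in lock-step with vectorised binomial
    draws; deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    two_n = 2 * config.diploid_size
    n_rep = config.replicates
    counts = np.full(n_rep, round(config.initial_frequency * two_n), dtype=np.int64)
    absorbed_at = np.full(n_rep, -1, dtype=np.int64)
    fixed = np.zeros(n_rep, dtype=bool)

    done = (counts == 0) | (counts == two_n)
    absorbed_at[done] = 0
    fixed[done & (counts == two_n)] = True
    seg_at: dict[int, float] = {}
    checkpoint_set = set(checkpoints)
    if 0 in checkpoint_set:
        seg_at[0] = float((~done).mean())

    for gen in range(1, config.horizon + 1):
        active = ~done
        if not active.any():
            # all absorbed; remaining checkpoints are zero
            for cp in sorted(checkpoint_set):
                if cp >= gen and cp not in seg_at:
                    seg_at[cp] = 0.0
            break
        counts[active] = rng.binomial(two_n, counts[active] / two_n)
        newly = active & ((counts == 0) | (counts == two_n))
        absorbed_at[newly] = gen
        fixed[newly & (counts == two_n)] = True
        done |= newly
        if gen in checkpoint_set:
            seg_at[gen] = float((~done).mean())

    absorbed = absorbed_at >= 0
    times = absorbed_at[absorbed].astype(float)
    mean_t = float(times.mean()) if times.size else float("nan")
    se = float(times.std(ddof=1) / np.sqrt(times.size)) if times.size > 1 else float("nan")
    return AbsorptionStats(
        mean_absorption_time=mean_t,
        standard_error=se,
        fixation_fraction=float(fixed.mean()),
        loss_fraction=float((absorbed & ~fixed).mean()),
        unabsorbed_fraction=float((~absorbed).mean()),
        segregating_fraction_at=dict(sorted(seg_at.items())),
        n_replicates=n_rep,
    )


def _transition_matrix(two_n: int) -> np.ndarray:
    """Binomial transition matrix over allele counts 0..2N (rows: from)."""
    from scipy.stats import binom

    counts = np.arange(two_n + 1)
    p = counts / two_n
    return binom.pmf(counts[None, :], two_n, p[:, None])


def markov_absorption_oracle(
    diploid_size: int,
    initial_count: int,
    checkpoints: tuple[int, ...] = (),
) -> dict:
    """Exact absorption expectations from the finite Markov chain.

    Solves (I - Q) t = 1 over the transient states 1..2N-1 for expected
    absorption times, solves the analogous system for fixation
    probabilities (which equal i/2N by the neutral martingale — kept as a
    cross-check), and computes exact P(segregating at generation g) by
    repeated multiplication with the transient block. Dense linear algebra;
    intended for 2N up to ~400.
    """
    two_n = 2 * diploid_size
    if two_n > 400:
        raise ValueError(f"state space too large: 2N = {two_n} > 400")
    if not 0 <= initial_count <= two_n:
        raise ValueError("initial_count must be in [0, 2N]")

    if initial_count in (0, two_n):
        return {
            "expected_absorption_time": 0.0,
            "fixation_probability": float(initial_count == two_n),
            "segregating_at": {int(g): 0.0 for g in checkpoints},
        }

    P = _transition_matrix(two_n)
    Q = P[1:-1, 1:-1]  # transient block
    n_t = two_n - 1
    I = np.eye(n_t)
    t = np.linalg.solve(I - Q, np.ones(n_t))
    fix = np.linalg.solve(I - Q, P[1:-1, -1])

    seg: dict[int, float] = {}
    if checkpoints:
        v = np.zeros(n_t)
        v[initial_count - 1] = 1.0
        gen = 0
        for cp in sorted(set(int(c) for c in checkpoints)):
            while gen < cp:
                v = v @ Q
                gen += 1
            seg[cp] = float(v.sum())

    return {
        "expected_absorption_time": float(t[initial_count - 1]),
        "fixation_probability": float(fix[initial_count - 1]),
        "segregating_at": seg,
    }


def segregating_fraction(
    config: WFConfig, checkpoints: tuple[int, ...]
) -> dict[int, tuple[float, float, float]]:
    """Fraction of replicate loci still segregating at each checkpoint.

    Returns ``{generation: (fraction, ci_low, ci_high)}`` with 95%
    Clopper-Pearson intervals. Fractions are non-increasing in time
    (absorption is irreversible).
    """
    from scipy.stats import beta

    if any(cp > config.horizon for cp in checkpoints):
        raise ValueError("checkpoints must not exceed max_generations")
    stats = simulate_absorption(config, checkpoints=tuple(checkpoints))
    n = config.replicates
    out: dict[int, tuple[float, float, float]] = {}
    for cp, frac in stats.segregating_fraction_at.items():
        k = round(frac * n)
        lo = beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi = beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
        out[cp] = (frac, float(lo), float(hi))
    return out


@dataclass(frozen=True)
class GeneFlowConfig:
    """Two-population divergence-with-gene-flow settings.

    ``hybridisation_rate`` m is the per-generation fraction of each
    population's gamete pool drawn from the other population.
    """

    populations: tuple[int, int]
    hybridisation_rate: float
    duration: int
    n_loci: int = 1000
    initial_frequency: float | np.ndarray = 0.5
    record_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) != 2 or min(self.populations) < 1:
            raise ValueError("populations must be two diploid sizes >= 1")
        if not 0.0 <= self.hybridisation_rate <= 0.5:
            raise ValueError("hybridisation_rate must be in [0, 0.5]")
        if self.duration < 1 or self.n_loci < 1:
            raise ValueError("duration and n_loci must be >= 1")


@dataclass(frozen=True)
class SharedPolyStats:
    """Time series of marginal and joint polymorphism fractions."""

    generations: np.ndarray
    segregating_pop1: np.ndarray
    segregating_pop2: np.ndarray
    segregating_joint: np.ndarray

    def final_joint(self) -> float:
        return float(self.segregating_joint[-1])


def simulate_divergence_with_geneflow(config: GeneFlowConfig) -> SharedPolyStats:
    """Two populations drift apart from a shared ancestral frequency while
    exchanging gametes at rate m per generation.

    Each generation, population i's gamete pool frequency is
    (1 - m) p_i + m p_j, then 2N_i copies are drawn binomially. A locus
    counts as jointly shared while both alleles segregate in both
    populations. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.populations
    m = config.hybridisation_rate
    p0 = np.broadcast_to(
        np.asarray(config.initial_frequency, dtype=float), (config.n_loci,)
    ).copy()
    p1, p2 = p0.copy(), p0.copy()

    gens, s1, s2, sj = [], [], [], []

    def record(gen: int) -> None:
        seg1 = (p1 > 0) & (p1 < 1)
        seg2 = (p2 > 0) & (p2 < 1)
        gens.append(gen)
        s1.append(seg1.mean())
        s2.append(seg2.mean())
        sj.append((seg1 & seg2).mean())

    record(0)
    for gen in range(1, config.duration + 1):
        pool1 = (1 - m) * p1 + m * p2
        pool2 = (1 - m) * p2 + m * p1
        p1 = rng.binomial(2 * n1, pool1) / (2 * n1)
        p2 = rng.binomial(2 * n2, pool2) / (2 * n2)
        if gen % config.record_every == 0 or gen == config.duration:
            record(gen)

    return SharedPolyStats(
        generations=np.array(gens),
        segregating_pop1=np.array(s1),
        segregating_pop2=np.array(s2),
        segregating_joint=np.array(sj),
    )
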