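"""Independent reference implementations.

Two slower routes exist for every headline quantity of the package:

* :func:`solve_fixation` computes the absorption probability of the
  explicit (N+1)-state birth-death chain by a direct linear solve of the
  first-step equations — no product formula, no log-space tricks.
* :func:`simulate_stationary` runs the full mutation-selection process
  (pairwise-comparison imitation plus rare uniform mutation) one step at
  a time and time-averages the strategy frequencies, which converges to
  the embedded-chain stationary distribution as the mutation rate
  vanishes.

Both exist to cross-validate the fast implementations, never to replace
them.  The simulation's inner loop is numba-compiled so that the
10^7-step runs the small-mutation regime demands remain cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import solve_banded

from .games import MatrixGame
from .update_rules import FitnessMap, ImitationRule

__all__ = [
    "BirthDeathChain",
    "SimConfig",
    "SimulationResult",
    "pairwise_chain",
    "moran_chain",
    "solve_fixation",
    "simulate_stationary",
]


@dataclass(frozen=True)
class BirthDeathChain:
    """Explicit transition probabilities of the mutant-count chain.

    ``t_plus[i-1]``/``t_minus[i-1]`` are the probabilities that the
    number of mutants moves from i to i+1 / i-1 in one step, i = 1..N-1;
    states 0 and N are absorbing.
    """

    N: int
    t_plus: np.ndarray
    t_minus: np.ndarray

    def __post_init__(self) -> None:
        tp = np.asarray(self.t_plus, dtype=float)
        tm = np.asarray(self.t_minus, dtype=float)
        if tp.shape != (self.N - 1,) or tm.shape != (self.N - 1,):
            raise ValueError("t_plus and t_minus must have length N-1")
        if np.any(tp < 0) or np.any(tm < 0) or np.any(tp + tm > 1 + 1e-12):
            raise ValueError("transition probabilities must satisfy 0 <= T+ + T- <= 1")
        object.__setattr__(self, "t_plus", tp)
        object.__setattr__(self, "t_minus", tm)


def pairwise_chain(profile, rule: ImitationRule) -> BirthDeathChain:
    """Birth-death chain of the pairwise-comparison process.

    T+-(i) = i (N - i) / N^2 * g(+-beta * delta_i): pick a focal and a
    model of opposite types, then imitate with probability g.  The
    neutral factor cancels from fixation probabilities but belongs in
    the explicit chain.
    """
    N = profile.N
    i = np.arange(1, N, dtype=float)
    neutral = i * (N - i) / N**2
    x = rule.beta * profile.delta
    return BirthDeathChain(N, neutral * rule.g(x), neutral * rule.g(-x))


def moran_chain(profile, fmap: FitnessMap) -> BirthDeathChain:
    """Birth-death chain of the frequency-dependent Moran process:
    reproduce proportional to fitness, replace a uniformly chosen
    individual."""
    N = profile.N
    if profile.pi_a is None or profile.pi_b is None:
        raise ValueError("Moran chain needs absolute payoffs in the profile")
    i = np.arange(1, N, dtype=float)
    lf_a = fmap.log_fitness(profile.pi_a)
    lf_b = fmap.log_fitness(profile.pi_b)
    # work with fitnesses normalized by the max to avoid overflow
    m = np.maximum(lf_a, lf_b)
    fa = np.exp(lf_a - m)
    fb = np.exp(lf_b - m)
    tot = i * fa + (N - i) * fb
    t_plus = (i * fa / tot) * (N - i) / N
    t_minus = ((N - i) * fb / tot) * i / N
    return BirthDeathChain(N, t_plus, t_minus)


def solve_fixation(chain: BirthDeathChain) -> float:
    """Absorption probability at state N starting from one mutant.

    First-step analysis gives the tridiagonal system
    ``T+ u_{i+1} - (T+ + T-) u_i + T- u_{i-1} = 0`` with u_0 = 0,
    u_N = 1, solved directly.
    """
    N = chain.N
    tp, tm = chain.t_plus, chain.t_minus
    if np.any(tp <= 0):
        raise ValueError("some T+ is zero: the interior is absorbing, fixation ill-posed")
    m = N - 1
    ab = np.zeros((3, m))
    ab[0, 1:] = tp[:-1]  # superdiagonal
    ab[1, :] = -(tp + tm)  # diagonal
    ab[2, :-1] = tm[1:]  # subdiagonal
    rhs = np.zeros(m)
    rhs[-1] = -tp[-1]  # u_N = 1
    u = solve_banded((1, 1), ab, rhs)
    return float(u[0])


@dataclass(frozen=True)
class SimConfig:
    """Full mutation-selection simulation parameters.

    ``mu`` must sit deep in the small-mutation regime (N mu log N << 1)
    for the time averages to be comparable with the embedded chain; a
    warning is emitted otherwise.
    """

    game: MatrixGame
    rule: ImitationRule
    N: int
    mu: float
    steps: int
    burn_in: int = 0
    seed: int = 0
    blocks: int = 100

    def __post_init__(self) -> None:
        if not isinstance(self.game, MatrixGame):
            raise TypeError("simulate_stationary supports two-player matrix games")
        if not (0 < self.mu < 1):
            raise ValueError("mutation probability mu must be in (0, 1)")
        if self.steps < self.blocks:
            raise ValueError("steps must be at least the number of blocks")
        if self.N * self.mu * np.log(self.N) > 0.1:
            warnings.warn(
                f"N*mu*log(N) = {self.N * self.mu * np.log(self.N):.3g} is not small; "
                "embedded-chain comparisons will be biased",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimulationResult:
    """Time-averaged strategy frequencies with block-bootstrap SEs.

    ``frequencies`` averages over every step and therefore carries an
    O(mu)-order bias from polymorphic excursions (failed invasions park
    a mutant lineage in the population for a while even when it never
    fixes).  ``frequencies_monomorphic`` conditions on the population
    being monomorphic — the construct the embedded chain approximates —
    and is the estimator to compare against its stationary
    distribution.  ``monomorphic_fraction`` diagnoses the small-mutation
    regime.
    """

    frequencies: np.ndarray
    se: np.ndarray
    frequencies_monomorphic: np.ndarray
    se_monomorphic: np.ndarray
    monomorphic_fraction: float
    block_means: np.ndarray
    monomorphic_entries: np.ndarray | None = None


_RULE_FERMI, _RULE_ERF = 0, 1


@njit(cache=True)
def _sim_loop(payoffs, N, beta, mu, steps, burn_in, rule_kind, counts, nblocks, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = payoffs.shape[0]
    block_len = steps // nblocks
    block_sums = np.zeros((nblocks, n))
    block_mono = np.zeros((nblocks, n))
    entries = np.zeros(n, dtype=np.int64)
    last_mono = -1
    mono_steps = 0
    for step in range(burn_in + steps):
        # focal individual, uniform over the population
        u = np.random.randint(0, N)
        f = 0
        acc = counts[0]
        while u >= acc:
            f += 1
            acc += counts[f]
        if np.random.random() < mu:
            counts[f] -= 1
            counts[np.random.randint(0, n)] += 1
        else:
            # model uniform among the other N-1 individuals
            v = np.random.randint(0, N - 1)
            if v >= u:
                v += 1
            m = 0
            acc = counts[0]
            while v >= acc:
                m += 1
                acc += counts[m]
            if m != f:
                pi_f = 0.0
                pi_m = 0.0
                for s in range(n):
                    pi_f += payoffs[f, s] * counts[s]
                    pi_m += payoffs[m, s] * counts[s]
                pi_f = (pi_f - payoffs[f, f]) / (N - 1)
                pi_m = (pi_m - payoffs[m, m]) / (N - 1)
                x = beta * (pi_m - pi_f)
                if rule_kind == 0:
                    p = 1.0 / (1.0 + np.exp(-x))
                else:
                    p = 0.5 * (1.0 + math.erf(x))
                if np.random.random() < p:
                    counts[f] -= 1
                    counts[m] += 1
        if step >= burn_in:
            t = step - burn_in
            b = t // block_len
            if b >= nblocks:
                b = nblocks - 1
            for s in range(n):
                block_sums[b, s] += counts[s]
                if counts[s] == N:
                    block_mono[b, s] += 1.0
                    mono_steps += 1
                    if s != last_mono:
                        entries[s] += 1
                        last_mono = s
    return block_sums, block_mono, entries, mono_steps


def simulate_stationary(config: SimConfig) -> SimulationResult:
    """Time-averaged strategy frequencies of the full stochastic process.

    Each elementary step picks a uniformly random focal individual; with
    probability ``mu`` it mutates to a strategy chosen uniformly among
    all n (possibly its own — this merely rescales the effective
    mutation rate), otherwise it compares payoffs with a model chosen
    uniformly among the other N-1 individuals and imitates with
    probability g(beta * (pi_model - pi_focal)).

    Standard errors come from a bootstrap over contiguous blocks
    (successive states are strongly autocorrelated, so per-step errors
    would be wild underestimates).
    """
    rule = config.rule
    if rule.name == "fermi":
        kind = _RULE_FERMI
    elif rule.name == "erf":
        kind = _RULE_ERF
    else:
        raise ValueError("the compiled simulator supports the fermi and erf rules")
    n = config.game.n
    N = config.N
    counts = np.zeros(n, dtype=np.int64)
    base = N // n
    counts[:] = base
    counts[: N - base * n] += 1
    block_sums, block_mono, entries, mono_steps = _sim_loop(
        config.game.payoffs,
        N,
        float(rule.beta),
        float(config.mu),
        int(config.steps),
        int(config.burn_in),
        kind,
        counts,
        int(config.blocks),
        int(config.seed) % (2**31 - 1),
    )
    block_len = config.steps // config.blocks
    lens = np.full(config.blocks, block_len, dtype=float)
    lens[-1] += config.steps - block_len * config.blocks
    block_means = block_sums / (lens[:, None] * N)
    freq = block_means.mean(axis=0)

    boot_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB00)))
    nboot = 1000
    idx = boot_rng.integers(0, config.blocks, size=(nboot, config.blocks))
    boot = block_means[idx].mean(axis=1)
    se = boot.std(axis=0, ddof=1)

    mono_total = block_mono.sum(axis=0)
    freq_mono = mono_total / max(mono_total.sum(), 1.0)
    # ratio estimator over resampled blocks, with a Poisson floor: a
    # state visited in only a few excursions carries sampling noise of
    # order p * sqrt(2 / #visits) that contiguous blocks cannot resolve
    boot_counts = block_mono[idx].sum(axis=1)
    boot_mono = boot_counts / np.maximum(boot_counts.sum(axis=1, keepdims=True), 1.0)
    se_mono = np.maximum(
        boot_mono.std(axis=0, ddof=1),
        freq_mono * np.sqrt(2.0 / np.maximum(entries, 1)),
    )
    return SimulationResult(
        frequencies=freq,
        se=se,
        frequencies_monomorphic=freq_mono,
        se_monomorphic=se_mono,
        monomorphic_fraction=mono_steps / config.steps,
        block_means=block_means,
        monomorphic_entries=entries,
    )
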