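"""Imitation rules, payoff-to-fitness maps, and fixation probabilities.

Under a pairwise-comparison process, a focal individual adopts the
strategy of a randomly chosen model with probability ``g(beta * (pi_model
- pi_focal))``, where ``g`` is an increasing *imitation function* and
``beta >= 0`` the selection intensity.  For a single mutant invading a
resident population the resulting birth-death chain has the classic
fixation probability

    rho = 1 / (1 + sum_{k=1}^{N-1} exp(S_k)),
    S_k = sum_{j<=k} log gamma_j,
    gamma_j = T^-(j) / T^+(j) = g(-beta * delta_j) / g(beta * delta_j),

where ``delta_j`` is the payoff difference at mutant count ``j``.  The
neutral sampling factor ``j (N - j) / N^2`` in the transition rates
cancels in ``gamma`` and never enters here.

Everything is carried in log space and aggregated with log-sum-exp: the
quantity the dynamics depends on is a product of transition-probability
ratios whose factors span hundreds of orders of magnitude at strong
selection, and log-space evaluation keeps it exact instead of capping
``beta`` ad hoc.  For the Fermi rule ``log gamma = -beta * delta``
identically, so no finite ``beta`` can overflow; rules whose ``g``
underflows to an exact zero raise :class:`OverflowSignal` so callers can
shrink ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.special import erf as _erf, erfcx as _erfcx, expit as _expit, logsumexp

__all__ = [
    "OverflowSignal",
    "ImitationRule",
    "FitnessMap",
    "FixationResult",
    "fermi",
    "log_fermi",
    "erf_imitation",
    "log_erf_imitation",
    "fermi_rule",
    "erf_rule",
    "custom_rule",
    "log_gamma_ratio",
    "fixation_probability",
    "moran_fixation",
    "pair_fixation",
]


class OverflowSignal(ArithmeticError):
    """A fixation computation left the representable log-domain range.

    Raised when an imitation function evaluates to exactly 0 at a finite
    argument (its log is -inf) or a cumulative log-ratio is non-finite.
    The caller is expected to reduce the selection intensity.
    """


# -- imitation functions ----------------------------------------------


def fermi(x):
    """Fermi (logistic) imitation function ``1 / (1 + exp(-x))``."""
    return _expit(x)


def log_fermi(x):
    """``log fermi(x) = -log(1 + exp(-x))``, stable for any float x."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def erf_imitation(x):
    """Rescaled error function ``(1 + erf(x)) / 2``."""
    return 0.5 * (1.0 + _erf(x))


def log_erf_imitation(x):
    """Log of the rescaled error function, accurate deep in the left tail.

    For x << 0, ``g(x) = erfc(-x)/2`` underflows; using the scaled
    complement ``erfcx(t) = exp(t^2) erfc(t)`` gives
    ``log g(x) = log(erfcx(-x)/2) - x^2`` without intermediate underflow.
    """
    x = np.asarray(x, dtype=float)
    neg = x < -1.0
    out = np.empty_like(x)
    xs = np.where(neg, -1.0, x)  # safe arg for the direct branch
    out[...] = np.log(0.5 * (1.0 + _erf(xs)))
    xt = np.where(neg, x, -1.0)
    out = np.where(neg, np.log(0.5 * _erfcx(-xt)) - xt * xt, out)
    return out


@dataclass(frozen=True)
class ImitationRule:
    """An imitation function ``g`` with its log-domain twin and a
    selection intensity.

    ``g`` maps the scaled payoff difference ``beta * delta`` to an
    adoption probability in [0, 1]; it must be strictly increasing with
    limits 0 and 1.  ``log_linear`` marks rules for which
    ``log g(x) - log g(-x) == x`` exactly (the Fermi function), which
    downstream code exploits for exact strong-selection classification.
    """

    name: str
    g: Callable
    log_g: Callable
    beta: float
    log_linear: bool = False

    def with_beta(self, beta: float) -> "ImitationRule":
        return replace(self, beta=beta)

    def log_gamma(self, delta):
        """Vectorised ``log gamma = log g(-beta*delta) - log g(beta*delta)``."""
        x = self.beta * np.asarray(delta, dtype=float)
        if self.log_linear:
            return -x
        return self.log_g(-x) - self.log_g(x)


def fermi_rule(beta: float) -> ImitationRule:
    return ImitationRule("fermi", fermi, log_fermi, beta, log_linear=True)


def erf_rule(beta: float) -> ImitationRule:
    return ImitationRule("erf", erf_imitation, log_erf_imitation, beta)


def custom_rule(
    g: Callable, log_g: Callable | None = None, beta: float = 1.0, name: str = "custom"
) -> ImitationRule:
    """Wrap a user-supplied imitation function.

    If ``log_g`` is omitted it is derived as ``log(g(x))``, which loses
    accuracy (and eventually underflows to -inf, triggering
    :class:`OverflowSignal`) for strongly negative arguments.
    """
    if log_g is None:
        def log_g(x, _g=g):
            with np.errstate(divide="ignore"):
                return np.log(_g(np.asarray(x, dtype=float)))
    return ImitationRule(name, g, log_g, beta)


@dataclass(frozen=True)
class FitnessMap:
    """Payoff-to-fitness map for the Moran process.

    kind "exponential": f = exp(beta * pi); kind "linear": f = 1 + beta * pi,
    valid only while f stays positive over the payoffs encountered.
    """

    kind: str
    beta: float

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "exponential"):
            raise ValueError("kind must be 'linear' or 'exponential'")

    def with_beta(self, beta: float) -> "FitnessMap":
        return replace(self, beta=beta)

    def log_fitness(self, pi):
        pi = np.asarray(pi, dtype=float)
        if self.kind == "exponential":
            return self.beta * pi
        f = 1.0 + self.beta * pi
        if np.any(f <= 0):
            bad = int(np.argmax(f <= 0))
            raise ValueError(
                f"linear fitness 1 + beta*pi is non-positive at state {bad + 1} "
                f"(pi = {pi[bad]:g}, beta = {self.beta:g})"
            )
        return np.log(f)


@dataclass(frozen=True)
class FixationResult:
    """Fixation probability with its log-domain diagnostics.

    ``log_terms[k-1]`` is the partial sum S_k of log transition ratios;
    ``log_rho`` stays meaningful even when ``rho`` underflows to 0.
    """

    rho: float
    log_rho: float
    log_terms: np.ndarray


def log_gamma_ratio(rule: ImitationRule, delta: float) -> float:
    """Log backward/forward transition ratio at a single state."""
    lg = np.asarray(rule.log_gamma(delta), dtype=float)
    if not np.all(np.isfinite(lg)):
        raise OverflowSignal(
            f"imitation function underflowed at beta*delta = {rule.beta * delta:g}"
        )
    return float(lg) if lg.ndim == 0 else lg


def _fixation_from_log_gammas(log_gammas: np.ndarray) -> FixationResult:
    if not np.all(np.isfinite(log_gammas)):
        raise OverflowSignal("non-finite log transition ratio; reduce beta")
    S = np.cumsum(log_gammas)
    if not np.all(np.isfinite(S)):
        raise OverflowSignal("non-finite cumulative log-ratio; reduce beta")
    if np.max(S) < 700.0:
        # all terms representable: direct sum is exact at neutrality
        # (rho = 1/N to the last bit) and loses nothing elsewhere
        denom = 1.0 + np.sum(np.exp(S))
        return FixationResult(rho=1.0 / denom, log_rho=float(-np.log(denom)), log_terms=S)
    log_denom = np.logaddexp(0.0, logsumexp(S))
    return FixationResult(rho=float(np.exp(-log_denom)), log_rho=float(-log_denom), log_terms=S)


def fixation_probability(profile, rule: ImitationRule) -> FixationResult:
    """Fixation probability of a single mutant under pairwise comparison.

    At ``beta = 0`` this is exactly ``1/N`` for any game and rule.
    """
    return _fixation_from_log_gammas(np.asarray(rule.log_gamma(profile.delta), dtype=float))


def moran_fixation(profile, fmap: FitnessMap) -> FixationResult:
    """Fixation probability of a single mutant under the Moran process.

    The ratio of backward to forward rates is ``f_B(i) / f_A(i)``; for the
    exponential map this equals ``exp(-beta * delta_i)``, making the Moran
    process coincide with Fermi imitation at every selection intensity.
    """
    if fmap.kind == "exponential":
        log_gammas = -fmap.beta * profile.delta
    else:
        if profile.pi_a is None or profile.pi_b is None:
            raise ValueError("linear fitness map needs absolute payoffs in the profile")
        log_gammas = fmap.log_fitness(profile.pi_b) - fmap.log_fitness(profile.pi_a)
    return _fixation_from_log_gammas(np.asarray(log_gammas, dtype=float))


def pair_fixation(profile, process) -> FixationResult:
    """Dispatch on the process type (imitation rule or fitness map)."""
    if isinstance(process, ImitationRule):
        return fixation_probability(profile, process)
    if isinstance(process, FitnessMap):
        return moran_fixation(profile, process)
    raise TypeError(f"unsupported process type {type(process).__name__}")
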