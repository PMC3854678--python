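"""Small-mutation embedded Markov chain over monomorphic states.

When mutations are rare enough that each mutant fixes or goes extinct
before the next one appears, the population hops between monomorphic
states and the dynamics collapses to an n-state Markov chain whose
transitions are fixation probabilities: from a resident-i population, a
mutant of strategy j (one of the n-1 alternatives, chosen uniformly)
fixes with probability rho_{j->i}, so

    Lambda[i, j] = rho[j, i] / (n - 1)   for j != i.

The stationary distribution x(beta) of this chain is the long-run
abundance of each strategy and defines the abundance ranking studied
throughout the package.  This module also provides the two limiting
characterizations: the weak-selection ranking from the derivatives
dx/dbeta at beta = 0, and the strong-selection classification of which
fixation probabilities survive as beta -> infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .games import n_strategies, pairwise_profile
from .update_rules import FitnessMap, ImitationRule, OverflowSignal, pair_fixation

__all__ = [
    "FixationMatrix",
    "EmbeddedChain",
    "StationaryDistribution",
    "build_fixation_matrix",
    "build_chain",
    "stationary",
    "stationary_for_game",
    "WeakSelectionRanking",
    "weak_selection_ranking",
    "StrongSelectionLimit",
    "strong_selection_limit",
]


@dataclass(frozen=True)
class FixationMatrix:
    """All pairwise fixation probabilities at one selection intensity.

    ``rho[m, r]`` is the probability that a single mutant of strategy m
    fixes in a resident-r population; ``log_rho`` is its log, which stays
    informative when rho underflows.  Diagonal entries are NaN.
    """

    rho: np.ndarray
    log_rho: np.ndarray
    beta: float

    @property
    def n(self) -> int:
        return self.rho.shape[0]


@dataclass(frozen=True)
class EmbeddedChain:
    """Transition matrix over monomorphic states; rows sum to 1."""

    Lambda: np.ndarray

    @property
    def n(self) -> int:
        return self.Lambda.shape[0]


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run strategy abundances x(beta); nonnegative, sums to 1.

    ``flags`` records numerical events: "reducible" when some fixation
    probability underflowed to zero (strong selection) and the chain lost
    irreducibility, "nonunique" when several closed classes remained.
    """

    x: np.ndarray
    beta: float
    flags: tuple[str, ...] = ()


def _pair_profiles(game, N: int) -> dict[tuple[int, int], object]:
    """All ordered-pair invasion profiles; the reversed orientation is a
    mirror, not a recomputation."""
    n = n_strategies(game)
    profiles: dict[tuple[int, int], object] = {}
    for a in range(n):
        for b in range(a + 1, n):
            p = pairwise_profile(game, a, b, N)
            profiles[(a, b)] = p
            profiles[(b, a)] = p.mirror()
    return profiles


def build_fixation_matrix(game, process, N: int, beta: float | None = None, *, profiles=None) -> FixationMatrix:
    """Compute all n(n-1) pairwise fixation probabilities.

    ``process`` is an :class:`ImitationRule` or :class:`FitnessMap`;
    ``beta`` overrides its selection intensity if given.  ``profiles``
    may carry precomputed pair profiles (sweeps reuse them across the
    whole beta grid).
    """
    if beta is not None:
        process = process.with_beta(beta)
    n = n_strategies(game)
    if profiles is None:
        profiles = _pair_profiles(game, N)
    rho = np.full((n, n), np.nan)
    log_rho = np.full((n, n), np.nan)
    for (m, r), prof in profiles.items():
        try:
            res = pair_fixation(prof, process)
        except (OverflowSignal, ValueError) as exc:
            raise type(exc)(
                f"fixation of mutant {m} in resident {r} at beta={process.beta:g}: {exc}"
            ) from exc
        rho[m, r] = res.rho
        log_rho[m, r] = res.log_rho
    return FixationMatrix(rho=rho, log_rho=log_rho, beta=process.beta)


def build_chain(fm: FixationMatrix) -> EmbeddedChain:
    """Embedded chain over monomorphic states from a fixation matrix."""
    n = fm.n
    Lam = np.where(np.isnan(fm.rho), 0.0, fm.rho).T / (n - 1)
    np.fill_diagonal(Lam, 0.0)
    np.fill_diagonal(Lam, 1.0 - Lam.sum(axis=1))
    return EmbeddedChain(Lam)


def _closed_classes(Lam: np.ndarray) -> list[np.ndarray]:
    """Strongly connected components with no outgoing transitions."""
    mask = Lam > 0.0
    np.fill_diagonal(mask, False)
    ncomp, labels = connected_components(mask, directed=True, connection="strong")
    closed = []
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        outside = np.setdiff1d(np.arange(Lam.shape[0]), members)
        if not mask[np.ix_(members, outside)].any():
            closed.append(members)
    return closed


def _solve_stationary(Lam: np.ndarray) -> np.ndarray:
    """Stationary vector of a stochastic matrix by GTH elimination.

    Grassmann-Taksar-Heyman state reduction is Gaussian elimination on
    the balance equations rearranged to be subtraction-free: it touches
    only off-diagonal entries and computes every stationary component
    with full relative accuracy.  This matters here because at strong
    selection fixation probabilities span hundreds of orders of
    magnitude and the textbook solve (replace one equation of
    ``x (Lambda - I) = 0`` with the normalization) destroys the small
    components through cancellation in the ``1 - sum`` diagonal.
    """
    from scipy.special import logsumexp

    n = Lam.shape[0]
    with np.errstate(divide="ignore"):
        L = np.log(Lam)  # log transition probabilities; elimination is
    np.fill_diagonal(L, -np.inf)  # carried entirely in log space so that
    # components hundreds of orders of magnitude apart survive intact
    for k in range(n - 1, 0, -1):
        ls = logsumexp(L[k, :k])
        if ls == -np.inf:
            raise np.linalg.LinAlgError("no outflow during GTH reduction (reducible chain)")
        L[:k, k] -= ls
        L[:k, :k] = np.logaddexp(L[:k, :k], L[:k, k, None] + L[None, k, :k])
        np.fill_diagonal(L[:k, :k], -np.inf)
    logx = np.full(n, -np.inf)
    logx[0] = 0.0
    for k in range(1, n):
        logx[k] = logsumexp(logx[:k] + L[:k, k])
    x = np.exp(logx - logx.max())
    return x / x.sum()


def _eig_stationary(Lam: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(Lam.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    x = np.real(v[:, idx])
    return x / x.sum()


def stationary(chain: EmbeddedChain, method: str = "solve") -> StationaryDistribution:
    """Stationary distribution of the embedded chain.

    ``method`` is "solve" (linear solve, default) or "eig"
    (left-eigenvector of eigenvalue 1); the two agree to ~1e-10 on
    irreducible chains and serve as mutual checks.

    At strong selection some fixation probabilities underflow to exact
    zeros and the chain can become reducible; the distribution is then
    supported on the closed communicating class(es) and flagged.
    """
    Lam = chain.Lambda
    n = chain.n
    off = Lam[~np.eye(n, dtype=bool)]
    if np.all(off > 0.0):  # strictly positive transitions: irreducible
        closed = [np.arange(n)]
    else:
        closed = _closed_classes(Lam)
    flags: tuple[str, ...] = ()
    if len(closed) == 1 and len(closed[0]) == n:
        solver = _solve_stationary if method == "solve" else _eig_stationary
        try:
            x = solver(Lam)
        except np.linalg.LinAlgError:
            x = _eig_stationary(Lam)
            flags = ("fallback_eig",)
    else:
        # reducible: mass settles on closed classes only
        flags = ("reducible",)
        if len(closed) > 1:
            flags = flags + ("nonunique",)
        x = np.zeros(n)
        for members in closed:
            sub = Lam[np.ix_(members, members)]
            sub = sub / sub.sum(axis=1, keepdims=True)
            if len(members) == 1:
                xc = np.ones(1)
            else:
                try:
                    xc = _solve_stationary(sub)
                except np.linalg.LinAlgError:
                    xc = _eig_stationary(sub)
            x[members] = xc / len(closed)
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    return StationaryDistribution(x=x, beta=np.nan, flags=flags)


def stationary_for_game(game, process, N: int, beta: float, *, profiles=None,
                        method: str = "solve") -> StationaryDistribution:
    """Stationary abundances of a game at one selection intensity.

    For two strategies the distribution is computed directly from the
    *log* fixation probabilities, ``x_A = 1 / (1 + rho_B/rho_A)``, which
    stays exact when both probabilities underflow linear floats.
    """
    fm = build_fixation_matrix(game, process, N, beta, profiles=profiles)
    if fm.n == 2:
        # x_0 proportional to fixation of a 0-mutant in a 1-resident population
        from scipy.special import expit

        x0 = float(expit(fm.log_rho[0, 1] - fm.log_rho[1, 0]))
        return StationaryDistribution(x=np.array([x0, 1.0 - x0]), beta=beta)
    sd = stationary(build_chain(fm), method=method)
    return StationaryDistribution(x=sd.x, beta=beta, flags=sd.flags)


# -- weak selection ----------------------------------------------------


@dataclass(frozen=True)
class WeakSelectionRanking:
    """Derivatives dx_i/dbeta at beta = 0 and the ordering they induce.

    ``order`` lists strategy indices from most to least favored;
    ``tie_groups`` collects sets of strategies whose derivatives are
    indistinguishable at the achieved numerical precision; ``converged``
    is False when the step-halving check disagreed by more than 1e-4.
    """

    derivatives: np.ndarray
    order: tuple[int, ...]
    tie_groups: tuple[frozenset, ...]
    converged: bool
    step: float


def weak_selection_ranking(game, process, N: int, *, deviation_band=(1e-3, 1e-2)) -> WeakSelectionRanking:
    """Rank strategies by the derivative of the stationary distribution
    at beta = 0, estimated by finite differences with Richardson
    extrapolation.

    The step h is auto-tuned so that x(h) deviates from uniform by an
    amount inside ``deviation_band`` — large enough to rise above solver
    noise, small enough to stay in the linear regime.  Since x(0) is
    exactly uniform, one-sided differences at h and h/2 combine to a
    second-order estimate ``2 D(h/2) - D(h)``.
    """
    n = n_strategies(game)
    profiles = _pair_profiles(game, N)
    uniform = np.full(n, 1.0 / n)

    def x_at(b: float) -> np.ndarray:
        return stationary_for_game(game, process, N, b, profiles=profiles).x

    lo, hi = deviation_band
    target = np.sqrt(lo * hi)
    h = 1e-3
    dev = 0.0
    for _ in range(60):
        dev = float(np.max(np.abs(x_at(h) - uniform)))
        if dev == 0.0:
            h *= 10.0
            if h > 1e12:  # neutral game: derivatives are identically zero
                zero = np.zeros(n)
                return WeakSelectionRanking(
                    derivatives=zero,
                    order=tuple(range(n)),
                    tie_groups=(frozenset(range(n)),),
                    converged=True,
                    step=np.nan,
                )
            continue
        if lo <= dev <= hi:
            break
        h *= float(np.clip(target / dev, 0.1, 10.0))
    def richardson(h_: float) -> tuple[np.ndarray, float]:
        D1 = (x_at(h_) - uniform) / h_
        D2 = (x_at(h_ / 2) - uniform) / (h_ / 2)
        D3 = (x_at(h_ / 4) - uniform) / (h_ / 4)
        R1 = 2.0 * D2 - D1  # first-order error eliminated
        R2 = 2.0 * D3 - D2
        return R2, float(np.max(np.abs(R2 - R1)))

    deriv, disagreement = richardson(h)
    if disagreement > 1e-4:  # curvature-heavy game: one retry at a smaller step
        h /= 8.0
        deriv, disagreement = richardson(h)
    converged = disagreement <= 1e-4

    order = tuple(int(i) for i in np.argsort(-deriv, kind="stable"))
    tie_tol = max(1e-10, disagreement)
    tie_groups: list[frozenset] = []
    group = [order[0]]
    for a, b in zip(order, order[1:]):
        if abs(deriv[a] - deriv[b]) < tie_tol:
            group.append(b)
        else:
            if len(group) > 1:
                tie_groups.append(frozenset(group))
            group = [b]
    if len(group) > 1:
        tie_groups.append(frozenset(group))
    return WeakSelectionRanking(
        derivatives=deriv,
        order=order,
        tie_groups=tuple(tie_groups),
        converged=converged,
        step=h,
    )


# -- strong selection --------------------------------------------------


@dataclass(frozen=True)
class StrongSelectionLimit:
    """Classification of each pairwise fixation probability as beta -> inf.

    ``rho_inf[m, r]`` is the limiting fixation probability (0, 1, or an
    intermediate value when partial payoff sums vanish exactly);
    ``degenerate[m, r]`` marks pairs whose limit is decided by
    higher-order terms; ``chain`` is the limiting embedded chain.
    """

    rho_inf: np.ndarray
    degenerate: np.ndarray
    chain: EmbeddedChain
    exact: bool


def _log_linear(process) -> bool:
    if isinstance(process, ImitationRule):
        return process.log_linear
    if isinstance(process, FitnessMap):
        return process.kind == "exponential"
    return False


def strong_selection_limit(game, process, N: int, *, beta_ladder=None, rtol: float = 1e-9) -> StrongSelectionLimit:
    """Limiting fixation probabilities and embedded chain as beta -> inf.

    For log-linear processes (Fermi imitation, exponential Moran) the
    limit is exact: S_k = -beta * P_k with P_k the partial payoff-difference
    sums, so rho -> 1 iff every P_k > 0, rho -> 0 iff some P_k < 0, and
    exact zeros among the P_k leave a degenerate intermediate limit
    1 / (1 + #zeros).  Only the sign structure of the payoff differences
    matters, which is why the strong-selection flow between any two
    strategies runs toward the risk-dominant one.

    For general rules the limit is estimated on a geometric beta ladder
    (default 2^0 .. 2^15) with convergence declared at successive
    relative change below ``rtol``.
    """
    n = n_strategies(game)
    profiles = _pair_profiles(game, N)
    rho_inf = np.full((n, n), np.nan)
    degen = np.zeros((n, n), dtype=bool)

    if _log_linear(process):
        for (m, r), prof in profiles.items():
            P = np.cumsum(prof.delta)
            tol = 1e-12 * max(1.0, float(np.max(np.abs(prof.delta)), ))
            if np.any(P < -tol):
                rho_inf[m, r] = 0.0
            else:
                zeros = int(np.sum(np.abs(P) <= tol))
                rho_inf[m, r] = 1.0 / (1 + zeros)
                degen[m, r] = zeros > 0
        exact = True
    else:
        if beta_ladder is None:
            beta_ladder = 2.0 ** np.arange(0, 16)
        for (m, r), prof in profiles.items():
            prev = None
            val = np.nan
            for b in beta_ladder:
                try:
                    res = pair_fixation(prof, process.with_beta(float(b)))
                except (OverflowSignal, ValueError):
                    break
                val = res.rho
                if prev is not None and abs(val - prev) <= rtol * max(prev, 1e-300):
                    break
                prev = val
            rho_inf[m, r] = 0.0 if val < 1e-12 else val
            degen[m, r] = not (val < 1e-12 or abs(val - 1.0) < 1e-6)
        exact = False

    chain = build_chain(FixationMatrix(rho=rho_inf, log_rho=np.log(
        np.where(np.isnan(rho_inf) | (rho_inf <= 0), np.nan, rho_inf)), beta=np.inf))
    return StrongSelectionLimit(rho_inf=rho_inf, degenerate=degen, chain=chain, exact=exact)
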