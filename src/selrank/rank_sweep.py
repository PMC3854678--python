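"""Abundance curves over a selection-intensity grid and rank-change
detection.

The central question is whether the abundance ranking of strategies —
the ordering of the stationary distribution x(beta) of the embedded
chain — is stable as the selection intensity grows.  A *rank change* is
a crossing of two strategies' abundance curves at some beta > 0.  This
module sweeps x(beta) over a log-spaced grid whose upper end is adapted
to stay inside the representable range of the chosen imitation rule,
detects sign changes of pairwise abundance differences between grid
points, refines each crossing location by bisection, and provides
randomized searches for the two headline phenomena: a 2-strategy
3-player game whose ranking is invariant under the Fermi rule but not
under the erf rule, and a 3x3 two-player game whose weak- and
strong-selection rankings agree while the ranking still changes at
intermediate selection intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedded_chain import (
    _pair_profiles,
    stationary_for_game,
    weak_selection_ranking,
)
from .games import MatrixGame, MultiplayerPayoffTable, n_strategies
from .update_rules import OverflowSignal, erf_rule, fermi_rule

__all__ = [
    "BetaGrid",
    "AbundanceCurve",
    "CrossingEvent",
    "RankChangeReport",
    "DegenerateGameError",
    "adaptive_beta_max",
    "study_beta_max",
    "abundance_evaluator",
    "sweep",
    "detect_crossings",
    "rank_change_report",
    "SearchResult",
    "find_rule_sensitive_game",
    "find_intermediate_crossing_game",
]

DEFAULT_BETA_MIN = 1e-3
DEFAULT_BETA_CAP = 1e3
DEFAULT_GRID_POINTS = 200


class DegenerateGameError(ValueError):
    """The game overflows the rule already at negligible selection."""


@dataclass(frozen=True)
class BetaGrid:
    """Strictly increasing positive selection intensities."""

    values: np.ndarray
    scale: str = "log"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("grid must be a nonempty 1-d array")
        if not np.all(np.isfinite(v)) or np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be finite, positive, strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def beta_max(self) -> float:
        return float(self.values[-1])

    @classmethod
    def log(cls, lo: float = DEFAULT_BETA_MIN, hi: float = DEFAULT_BETA_CAP,
            num: int = DEFAULT_GRID_POINTS) -> "BetaGrid":
        return cls(np.geomspace(lo, hi, num), "log")

    @classmethod
    def linear(cls, lo: float, hi: float, num: int) -> "BetaGrid":
        return cls(np.linspace(lo, hi, num), "linear")

    def refined(self, factor: int) -> "BetaGrid":
        lo, hi = float(self.values[0]), float(self.values[-1])
        num = (self.values.size - 1) * factor + 1
        if self.scale == "log":
            return BetaGrid(np.geomspace(lo, hi, num), "log")
        return BetaGrid(np.linspace(lo, hi, num), "linear")


@dataclass(frozen=True)
class AbundanceCurve:
    """Stationary abundances x[t, i] along a beta grid.

    ``flags[t]`` carries the stationary solver's numerical flags at grid
    point t (reducibility at strong selection etc.).
    """

    grid: BetaGrid
    x: np.ndarray
    flags: tuple[tuple[str, ...], ...] = field(repr=False, default=())

    @property
    def n(self) -> int:
        return self.x.shape[1]


@dataclass(frozen=True)
class CrossingEvent:
    """One rank change: strategies ``pair`` swap their abundance order
    inside ``bracket``; ``beta_star`` is the refined crossing point and
    ``direction`` the strategy that comes out on top."""

    pair: tuple[int, int]
    bracket: tuple[float, float]
    beta_star: float
    direction: int


@dataclass(frozen=True)
class RankChangeReport:
    events: tuple[CrossingEvent, ...]
    top_changes: int
    degenerate_flags: tuple[str, ...] = ()

    @property
    def total_count(self) -> int:
        return len(self.events)


def _probe(game, process, N: int, beta: float, profiles) -> bool:
    """True when every pairwise fixation is finite in log domain."""
    from .update_rules import pair_fixation

    try:
        for prof in profiles.values():
            pair_fixation(prof, process.with_beta(beta))
    except (OverflowSignal, ValueError):
        return False
    return True


def adaptive_beta_max(game, process, N: int, cap: float = DEFAULT_BETA_CAP) -> float:
    """Largest usable selection intensity, at 1% precision.

    Mirrors the study protocol of sweeping beta on [0, beta_max] with
    beta_max adjusted to avoid arithmetic overflow.  Rules evaluated in
    pure log space (Fermi, erf, exponential Moran) never overflow, so
    the probe returns ``cap`` immediately; rules with a bounded validity
    domain (linear Moran fitness) or user rules without a stable log are
    bracketed by doubling and refined by bisection.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    profiles = _pair_profiles(game, N)
    if _probe(game, process, N, cap, profiles):
        return cap
    lo = 1e-6
    if not _probe(game, process, N, lo, profiles):
        raise DegenerateGameError(
            "fixation overflows already at beta = 1e-6; the game/rule pair is degenerate"
        )
    hi = lo
    while hi < cap:
        nxt = min(hi * 2, cap)
        if _probe(game, process, N, nxt, profiles):
            lo = hi = nxt
        else:
            hi = nxt
            break
    while (hi - lo) > 0.01 * lo:
        mid = np.sqrt(lo * hi)
        if _probe(game, process, N, mid, profiles):
            lo = mid
        else:
            hi = mid
    return float(lo)


def _log_gamma_grid(process, profile, betas: np.ndarray) -> np.ndarray:
    """log transition ratios for all grid betas at once, shape (T, N-1)."""
    from .update_rules import FitnessMap, ImitationRule

    if isinstance(process, ImitationRule):
        X = np.outer(betas, profile.delta)
        if process.log_linear:
            return -X
        return process.log_g(-X) - process.log_g(X)
    if isinstance(process, FitnessMap):
        if process.kind == "exponential":
            return -np.outer(betas, profile.delta)
        fa = 1.0 + np.outer(betas, profile.pi_a)
        fb = 1.0 + np.outer(betas, profile.pi_b)
        if np.any(fa <= 0) or np.any(fb <= 0):
            raise ValueError("linear fitness non-positive inside the grid; lower beta_max")
        return np.log(fb) - np.log(fa)
    raise TypeError(f"unsupported process type {type(process).__name__}")


def _batch_fixation(process, profiles, betas: np.ndarray, n: int):
    """rho and log(rho) for every ordered pair at every grid point."""
    T = betas.size
    rho = np.full((T, n, n), np.nan)
    log_rho = np.full((T, n, n), np.nan)
    for (m, r), prof in profiles.items():
        lg = _log_gamma_grid(process, prof, betas)
        if not np.all(np.isfinite(lg)):
            raise OverflowSignal(
                f"non-finite log transition ratio for pair ({m},{r}) inside the grid"
            )
        S = np.cumsum(lg, axis=1)
        smax = S.max(axis=1)
        safe = smax < 700.0
        denom = 1.0 + np.sum(np.exp(np.where(safe[:, None], S, -np.inf)), axis=1)
        lr = np.where(safe, -np.log(denom), np.nan)
        if not np.all(safe):
            from scipy.special import logsumexp

            hard = ~safe
            lr[hard] = -np.logaddexp(0.0, logsumexp(S[hard], axis=1))
        rho[:, m, r] = np.exp(lr)
        log_rho[:, m, r] = lr
    return rho, log_rho


LOG_DBL_MAX = 709.78  # log of the largest double; the classic overflow wall


def study_beta_max(game, process, N: int, cap: float = DEFAULT_BETA_CAP,
                   threshold: float = LOG_DBL_MAX) -> float:
    """Upper end of the study grid, emulating the classic overflow wall.

    Crossing counts depend on the range of selection intensities
    surveyed.  The reference protocol sweeps beta on [0, beta_max] with
    beta_max adjusted so that the fixation-probability arithmetic stays
    inside double range when evaluated *without* log-space tricks, i.e.
    the largest cumulative log transition ratio stays below
    ``log(DBL_MAX)``.  Our log-space evaluation could go further, but a
    study that surveyed a wider beta range would count crossings in
    territory the reference statistics never saw, so the study grid
    stops where the classic arithmetic would have stopped.

    For log-linear rules S_k = -beta * P_k, giving the closed form
    ``beta_max = threshold / max_k(-P_k)``; other rules are bracketed by
    doubling and refined by geometric bisection to 1%.
    """
    from .update_rules import pair_fixation

    profiles = _pair_profiles(game, N)
    from .embedded_chain import _log_linear

    if _log_linear(process):
        M = max(float(np.max(-np.cumsum(p.delta))) for p in profiles.values())
        return cap if M <= 0 else min(cap, threshold / M)

    def ok(beta: float) -> bool:
        try:
            for prof in profiles.values():
                res = pair_fixation(prof, process.with_beta(beta))
                if np.max(res.log_terms) > threshold:
                    return False
        except (OverflowSignal, ValueError):
            return False
        return True

    if ok(cap):
        return cap
    lo = 1e-6
    if not ok(lo):
        raise DegenerateGameError(
            "fixation overflows already at beta = 1e-6; the game/rule pair is degenerate"
        )
    hi = lo
    while hi < cap:
        nxt = min(hi * 2, cap)
        if ok(nxt):
            lo = hi = nxt
        else:
            hi = nxt
            break
    while (hi - lo) > 0.01 * lo:
        mid = float(np.sqrt(lo * hi))
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return float(lo)


def sweep(game, process, N: int, grid: BetaGrid, *, method: str = "solve",
          batch: bool = True) -> AbundanceCurve:
    """Stationary abundances at every grid point.

    Two independent code paths exist: ``batch=True`` (default)
    vectorizes the fixation computation over the whole grid per strategy
    pair; ``batch=False`` computes each grid point independently through
    :func:`stationary_for_game`.  They agree to ~1e-10 and serve as
    mutual regression checks.
    """
    profiles = _pair_profiles(game, N)
    n = n_strategies(game)
    betas = grid.values
    if not batch:
        X = np.empty((betas.size, n))
        flags = []
        for t, b in enumerate(betas):
            sd = stationary_for_game(game, process, N, float(b), profiles=profiles, method=method)
            X[t] = sd.x
            flags.append(sd.flags)
        return AbundanceCurve(grid=grid, x=X, flags=tuple(flags))

    from scipy.special import expit

    rho, log_rho = _batch_fixation(process, profiles, betas, n)
    if n == 2:
        X = np.empty((betas.size, n))
        x0 = expit(log_rho[:, 0, 1] - log_rho[:, 1, 0])
        X[:, 0] = x0
        X[:, 1] = 1.0 - x0
    else:
        X = _stationary_batch_gth(log_rho)
    return AbundanceCurve(grid=grid, x=X, flags=((),) * betas.size)


def _stationary_batch_gth(log_rho: np.ndarray) -> np.ndarray:
    """Stationary distributions for a stack of fixation matrices, by
    GTH state reduction carried in log space and vectorized over the
    grid axis.

    ``log_rho[t, m, r]`` is finite for every finite beta, so the
    embedded chain is always irreducible here and every component is
    obtained with full relative accuracy however small it is.
    """
    from scipy.special import logsumexp

    T, n, _ = log_rho.shape
    # log Lambda[t, i, j] = log rho[t, j, i] - log(n - 1)
    L = np.swapaxes(log_rho, 1, 2) - np.log(n - 1)
    ii = np.arange(n)
    L[:, ii, ii] = -np.inf
    for k in range(n - 1, 0, -1):
        ls = logsumexp(L[:, k, :k], axis=1)
        L[:, :k, k] -= ls[:, None]
        L[:, :k, :k] = np.logaddexp(
            L[:, :k, :k], L[:, :k, k, None] + L[:, None, k, :k]
        )
        kk = np.arange(k)
        L[:, kk, kk] = -np.inf
    logx = np.full((T, n), -np.inf)
    logx[:, 0] = 0.0
    for k in range(1, n):
        logx[:, k] = logsumexp(logx[:, :k] + L[:, :k, k], axis=1)
    x = np.exp(logx - logx.max(axis=1, keepdims=True))
    return x / x.sum(axis=1, keepdims=True)


def abundance_evaluator(game, process, N: int):
    """Closure beta -> x(beta), reusing precomputed pair profiles."""
    profiles = _pair_profiles(game, N)

    def evaluate(beta: float) -> np.ndarray:
        return stationary_for_game(game, process, N, beta, profiles=profiles).x

    return evaluate


def _refine(evaluate, i, j, lo, hi, d_lo, rel: float = 1e-6) -> float:
    """Bisect the sign change of x_i - x_j inside (lo, hi); every probe
    recomputes the full stationary distribution."""
    s_lo = np.sign(d_lo)
    while (hi - lo) > rel * lo:
        mid = float(np.sqrt(lo * hi))
        x = evaluate(mid)
        if np.sign(x[i] - x[j]) == s_lo:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def detect_crossings(curve: AbundanceCurve, tol: float = 1e-10, *, evaluate=None) -> RankChangeReport:
    """Count rank changes between all strategy pairs along the curve.

    A crossing is a sign change of ``x_i - x_j`` between consecutive grid
    points with the difference exceeding ``tol`` on both sides; grid
    values inside the tolerance band are flagged degenerate and never
    counted (tangencies and the exact tie at beta = 0 do not change the
    ranking).  If an ``evaluate`` callable (beta -> x) is supplied, each
    crossing is refined by bisection to 1e-6 relative precision in beta.
    """
    betas = curve.grid.values
    if betas.size < 2:
        raise ValueError("crossing detection needs at least two grid points")
    n = curve.n
    events: list[CrossingEvent] = []
    degenerate: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = curve.x[:, i] - curve.x[:, j]
            small = np.abs(d) <= tol
            if np.any(small):
                ts = np.flatnonzero(small)
                degenerate.append(
                    f"pair ({i},{j}): |x_i - x_j| <= tol at {ts.size} grid point(s) "
                    f"starting beta={betas[ts[0]]:g}"
                )
            sign_change = (np.sign(d[:-1]) * np.sign(d[1:]) < 0) & ~small[:-1] & ~small[1:]
            for t in np.flatnonzero(sign_change):
                lo, hi = float(betas[t]), float(betas[t + 1])
                if evaluate is not None:
                    beta_star = _refine(evaluate, i, j, lo, hi, d[t])
                else:
                    beta_star = float(np.sqrt(lo * hi))
                direction = j if d[t] > 0 else i
                events.append(CrossingEvent((i, j), (lo, hi), beta_star, direction))
    events.sort(key=lambda e: e.beta_star)

    # changes in the identity of the most abundant strategy: a counted
    # crossing in which the overtaken strategy led the population
    leaders = np.argmax(curve.x, axis=1)
    top = 0
    for e in events:
        t = int(np.searchsorted(betas, e.bracket[0]))
        overtaken = e.pair[0] if e.direction == e.pair[1] else e.pair[1]
        t_hi = min(t + 1, len(leaders) - 1)
        if leaders[t] == overtaken and leaders[t_hi] == e.direction:
            top += 1
    return RankChangeReport(events=tuple(events), top_changes=top,
                            degenerate_flags=tuple(degenerate))


def rank_change_report(game, process, N: int, grid: BetaGrid | None = None, *,
                       tol: float = 1e-10, refine: bool = True,
                       cap: float = DEFAULT_BETA_CAP) -> tuple[AbundanceCurve, RankChangeReport]:
    """Sweep a game and report its rank changes in one call.

    Without an explicit grid, a 200-point log grid from 1e-3 up to the
    game's :func:`study_beta_max` is used (the reference study protocol).
    """
    if grid is None:
        bmax = study_beta_max(game, process, N, cap)
        grid = BetaGrid.log(DEFAULT_BETA_MIN, bmax, DEFAULT_GRID_POINTS)
    curve = sweep(game, process, N, grid)
    evaluate = abundance_evaluator(game, process, N) if refine else None
    return curve, detect_crossings(curve, tol, evaluate=evaluate)


# -- randomized searches ----------------------------------------------


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a randomized game search; ``found`` is False when the
    attempt budget ran out (a value, not an error)."""

    found: bool
    game: object | None
    N: int
    attempts_used: int
    reports: dict = field(default_factory=dict)


def find_rule_sensitive_game(rng, d: int = 3, attempts: int = 10_000, *, N: int = 50,
                         grid: BetaGrid | None = None,
                         beta: float = 1.0) -> SearchResult:
    """Search for a 2-strategy d-player game whose abundance ranking is
    invariant under the Fermi rule but changes under the erf rule.

    Payoff tables are drawn with i.i.d. standard normal entries.  For
    two-player games (d = 2) ranking invariance holds for any imitation
    function, so the search must (and does) come up empty there.
    """
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    fermi_p = fermi_rule(beta)
    erf_p = erf_rule(beta)
    for attempt in range(1, attempts + 1):
        table = MultiplayerPayoffTable(rng.standard_normal(d), rng.standard_normal(d))
        try:
            _, rep_erf = rank_change_report(table, erf_p, N, grid, refine=False)
            if rep_erf.total_count < 1:
                continue
            _, rep_fermi = rank_change_report(table, fermi_p, N, grid, refine=False)
        except (OverflowSignal, ValueError):
            continue
        if rep_fermi.total_count == 0:
            return SearchResult(True, table, N, attempt,
                                {"fermi": rep_fermi, "erf": rep_erf})
    return SearchResult(False, None, N, attempts)


def _strict_order(x: np.ndarray, tol: float) -> tuple[int, ...] | None:
    order = np.argsort(-x, kind="stable")
    vals = x[order]
    if np.any(np.abs(np.diff(vals)) < tol):
        return None
    return tuple(int(i) for i in order)


def find_intermediate_crossing_game(rng, n: int = 3, attempts: int = 10_000, *, N: int = 100,
                             process=None, grid: BetaGrid | None = None,
                             tie_tol: float = 1e-6) -> SearchResult:
    """Search for an n-strategy two-player game whose weak- and
    strong-selection abundance rankings coincide while at least two rank
    changes occur at intermediate selection intensities (the ranking
    leaves the limiting order and returns to it).

    The weak-selection ranking orders the derivatives dx/dbeta at
    beta = 0; the strong-selection ranking is read off the abundances at
    the top of the adaptive beta grid.  Payoffs are i.i.d. Uniform(0,1).
    """
    if attempts < 1:
        raise ValueError("attempts must be >= 1")
    if process is None:
        process = fermi_rule(1.0)
    for attempt in range(1, attempts + 1):
        game = MatrixGame(rng.uniform(0.0, 1.0, size=(n, n)))
        try:
            curve, rep = rank_change_report(game, process, N, grid, refine=False)
            if rep.total_count < 2:
                continue
            weak = weak_selection_ranking(game, process, N)
            if weak.tie_groups:
                continue
            strong_order = _strict_order(curve.x[-1], tie_tol)
            if strong_order is None or strong_order != weak.order:
                continue
        except (OverflowSignal, ValueError):
            continue
        return SearchResult(True, game, N, attempt,
                            {"report": rep, "weak": weak, "order": strong_order})
    return SearchResult(False, None, N, attempts)
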