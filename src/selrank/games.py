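"""Game payoff structures and their reduction to pairwise invasion profiles.

Every evolutionary computation downstream (fixation probabilities, the
embedded Markov chain, abundance sweeps) consumes a single object: the
:class:`PairwiseProfile`, the sequence of payoff differences
``delta[i] = pi_A(i) - pi_B(i)`` between a mutant strategy A present in
``i`` copies and a resident strategy B filling the remaining ``N - i``
slots of a well-mixed population of size ``N``.  This module defines the
supported game families — symmetric two-player matrix games, d-player
two-strategy games given by payoff tables, and a parametric public-goods
game with punishment — and reduces each of them to that profile.

Payoffs assume everyone interacts with everyone else, excluding
self-interaction: a focal individual's payoff is the average over its
``N - 1`` potential co-players (two-player case) or over all groups of
``d - 1`` co-players drawn without replacement (multiplayer case).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "MatrixGame",
    "MultiplayerPayoffTable",
    "MultiplayerGameBundle",
    "PairwiseProfile",
    "matrix_pair_profile",
    "multiplayer_pair_profile",
    "pgg_punishment_game",
    "pairwise_profile",
    "n_strategies",
]


class InvalidPairError(ValueError):
    """Raised when a mutant/resident pair is ill-formed (e.g. A == B)."""


@dataclass(frozen=True)
class MatrixGame:
    """Symmetric two-player game: ``payoffs[i, j]`` is the payoff to a
    player of strategy ``i`` against strategy ``j``."""

    payoffs: np.ndarray
    strategies: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.payoffs, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"payoff matrix must be square, got shape {a.shape}")
        if a.shape[0] < 2:
            raise ValueError("a game needs at least two strategies")
        if not np.all(np.isfinite(a)):
            raise ValueError("payoff entries must be finite")
        if self.strategies is not None and len(self.strategies) != a.shape[0]:
            raise ValueError("strategy names do not match matrix size")
        object.__setattr__(self, "payoffs", a)

    @property
    def n(self) -> int:
        return self.payoffs.shape[0]

    def names(self) -> tuple[str, ...]:
        if self.strategies is not None:
            return self.strategies
        return tuple(str(i + 1) for i in range(self.n))

    def permuted(self, perm: np.ndarray) -> "MatrixGame":
        """Relabel strategies: new strategy ``k`` is old strategy ``perm[k]``."""
        perm = np.asarray(perm)
        names = None
        if self.strategies is not None:
            names = tuple(self.strategies[p] for p in perm)
        return MatrixGame(self.payoffs[np.ix_(perm, perm)], names)

    # -- serialization -------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "MatrixGame":
        df = _read_numeric_csv(path)
        names = None
        if df.columns.inferred_type not in ("integer", "floating", "mixed-integer-float"):
            names = tuple(str(c) for c in df.columns)
        return cls(df.to_numpy(dtype=float), names)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.payoffs, columns=list(self.names()))
        df.to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "MatrixGame":
        with open(path) as fh:
            obj = json.load(fh)
        names = tuple(obj["strategies"]) if obj.get("strategies") else None
        return cls(np.asarray(obj["payoffs"], dtype=float), names)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"strategies": list(self.names()), "payoffs": self.payoffs.tolist()},
                fh,
                indent=1,
            )


def _read_numeric_csv(path) -> pd.DataFrame:
    """Read a CSV payoff matrix, pointing at the offending cell on error.

    The first line is treated as a header of strategy names only when it
    is not fully numeric.
    """
    try:
        raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    first = raw.iloc[0]
    try:
        [float(v) for v in first]
        names = None
        data = raw
        offset = 1
    except (TypeError, ValueError):
        names = [str(v) for v in first]
        data = raw.iloc[1:].reset_index(drop=True)
        offset = 2
    numeric = data.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {i + offset}, column {j + 1}"
        )
    # pandas' fast string parser can be a ulp off; float() is correctly
    # rounded, which keeps CSV round trips bit-exact
    exact = pd.DataFrame(
        [[float(v) for v in row] for row in data.to_numpy()],
        columns=names if names is not None else range(numeric.shape[1]),
    )
    return exact


@dataclass(frozen=True)
class MultiplayerPayoffTable:
    """d-player two-strategy game.

    ``a[k]`` is the payoff to an A-player whose ``d - 1`` co-players
    include ``k`` A-players; ``b[k]`` the payoff to a B-player in the
    same situation, for ``k = 0 .. d-1``.
    """

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise ValueError("a and b must be 1-d vectors of equal length")
        if a.size < 2:
            raise ValueError("group size d must be at least 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("payoff entries must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def d(self) -> int:
        return self.a.size

    @classmethod
    def from_csv(cls, path) -> "MultiplayerPayoffTable":
        df = pd.read_csv(path)
        required = {"k", "a_k", "b_k"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns k, a_k, b_k")
        df = df.sort_values("k")
        k = df["k"].to_numpy()
        if not np.array_equal(k, np.arange(len(k))):
            raise ValueError(f"{path}: k column must enumerate 0..d-1")
        return cls(df["a_k"].to_numpy(dtype=float), df["b_k"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"k": np.arange(self.d), "a_k": self.a, "b_k": self.b}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class PairwiseProfile:
    """Payoff differences of a mutant A against a resident B.

    ``delta[i - 1] = pi_A(i) - pi_B(i)`` for ``i = 1 .. N-1`` copies of
    the mutant.  ``pi_a``/``pi_b`` are kept when available (the linear
    Moran map needs absolute payoffs, not just differences).
    """

    N: int
    delta: np.ndarray
    pi_a: np.ndarray | None = None
    pi_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be at least 2")
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (self.N - 1,):
            raise ValueError(f"delta must have length N-1 = {self.N - 1}")
        if not np.all(np.isfinite(d)):
            raise ValueError("delta must be finite")
        object.__setattr__(self, "delta", d)
        for name in ("pi_a", "pi_b"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != d.shape or not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} must be a finite length-(N-1) vector")
                object.__setattr__(self, name, v)

    def mirror(self) -> "PairwiseProfile":
        """Profile of the swapped pair (B invading A).

        ``delta_BA(i) = -delta_AB(N - i)``: i copies of B facing N - i
        copies of A is the same population state read from the other side.
        """
        pa = self.pi_b[::-1].copy() if self.pi_b is not None else None
        pb = self.pi_a[::-1].copy() if self.pi_a is not None else None
        return PairwiseProfile(self.N, -self.delta[::-1], pa, pb)


def matrix_pair_profile(game: MatrixGame, A: int, B: int, N: int) -> PairwiseProfile:
    """Reduce a matrix game to the invasion profile of strategy ``A``
    (mutant) against ``B`` (resident) in a population of size ``N``.

    With ``i`` mutants, each individual meets all other ``N - 1``
    individuals, never itself, so

    ``pi_A(i) = [a_AA (i-1) + a_AB (N-i)] / (N-1)``
    ``pi_B(i) = [a_BA i + a_BB (N-i-1)] / (N-1)``
    """
    if A == B:
        raise InvalidPairError("mutant and resident strategies must differ")
    if N < 2:
        raise ValueError("population size N must be at least 2")
    a = game.payoffs
    i = np.arange(1, N, dtype=float)
    pi_a = (a[A, A] * (i - 1) + a[A, B] * (N - i)) / (N - 1)
    pi_b = (a[B, A] * i + a[B, B] * (N - i - 1)) / (N - 1)
    return PairwiseProfile(N, pi_a - pi_b, pi_a, pi_b)


def multiplayer_pair_profile(table: MultiplayerPayoffTable, N: int) -> PairwiseProfile:
    """Invasion profile for a d-player two-strategy game.

    Groups of ``d`` are formed by sampling the focal individual's
    ``d - 1`` co-players uniformly without replacement from the other
    ``N - 1`` individuals, so the expected payoffs are hypergeometric
    mixtures of the table rows.
    """
    d = table.d
    if N < d:
        raise ValueError(f"population size N={N} is smaller than the group size d={d}")
    i = np.arange(1, N)[:, None]  # mutant counts, column
    k = np.arange(d)[None, :]  # A-co-players of the focal
    # focal A: the other N-1 individuals contain i-1 A's
    w_a = hypergeom.pmf(k, N - 1, i - 1, d - 1)
    # focal B: the other N-1 individuals contain i A's
    w_b = hypergeom.pmf(k, N - 1, i, d - 1)
    pi_a = w_a @ table.a
    pi_b = w_b @ table.b
    return PairwiseProfile(N, pi_a - pi_b, pi_a, pi_b)


@dataclass(frozen=True)
class MultiplayerGameBundle:
    """A set of strategies whose pairwise contests are d-player games.

    ``tables[(X, Y)]`` holds the payoff table for the ordered pair
    ``(X, Y)`` with X as the "A" role; the reversed pair is obtained by
    mirroring the profile, so only one orientation per pair is stored.
    """

    strategies: tuple[str, ...]
    tables: Mapping[tuple[str, str], MultiplayerPayoffTable] = field(repr=False)

    def __post_init__(self) -> None:
        d = {t.d for t in self.tables.values()}
        if len(d) != 1:
            raise ValueError("all tables in a bundle must share the group size d")
        for X, Y in self.tables:
            if X not in self.strategies or Y not in self.strategies:
                raise ValueError(f"table pair ({X}, {Y}) names unknown strategies")

    @property
    def n(self) -> int:
        return len(self.strategies)

    @property
    def d(self) -> int:
        return next(iter(self.tables.values())).d

    def pair_profile(self, A: int, B: int, N: int) -> PairwiseProfile:
        if A == B:
            raise InvalidPairError("mutant and resident strategies must differ")
        sA, sB = self.strategies[A], self.strategies[B]
        if (sA, sB) in self.tables:
            return multiplayer_pair_profile(self.tables[(sA, sB)], N)
        if (sB, sA) in self.tables:
            return multiplayer_pair_profile(self.tables[(sB, sA)], N).mirror()
        raise KeyError(f"no payoff table for pair ({sA}, {sB})")


def pgg_punishment_game(
    d: int,
    r: float,
    c: float,
    fine: float = 0.0,
    punish_cost: float = 0.0,
) -> MultiplayerGameBundle:
    """Compulsory public goods game with altruistic punishment.

    Groups of ``d`` play a public goods game: each contributor pays ``c``
    into a pool, the pool is multiplied by ``r`` (1 < r < d) and shared
    equally among all ``d`` members.  Strategies are cooperators (C, who
    contribute), defectors (D, who do not), and punishers (P, who
    contribute and additionally pay ``punish_cost`` per defector in their
    group to impose ``fine`` on each defector per punisher).

    Returns the three pairwise payoff tables, for the ordered pairs
    (C, D), (C, P) and (D, P), wrapped in a bundle.
    """
    import warnings

    if d < 2:
        raise ValueError("group size d must be at least 2")
    if c <= 0:
        raise ValueError("contribution cost c must be positive")
    if fine < 0 or punish_cost < 0:
        raise ValueError("fine and punish_cost must be nonnegative")
    if not (1 < r < d):
        warnings.warn(
            f"multiplication factor r={r} outside (1, d={d}): the public goods "
            "dilemma is degenerate",
            stacklevel=2,
        )

    k = np.arange(d)  # number of first-strategy co-players of the focal

    # (C, D): k cooperators among co-players; focal C makes k+1 contributors
    cd = MultiplayerPayoffTable(
        a=r * c * (k + 1) / d - c,
        b=r * c * k / d,
    )
    # (C, P): everyone contributes, no defectors to punish
    cp = MultiplayerPayoffTable(
        a=np.full(d, r * c - c),
        b=np.full(d, r * c - c),
    )
    # (D, P): k defector co-players; focal D faces d-1-k punishers,
    # focal P faces k defectors and is one of d-k contributors
    dp = MultiplayerPayoffTable(
        a=r * c * (d - 1 - k) / d - fine * (d - 1 - k),
        b=r * c * (d - k) / d - c - punish_cost * k,
    )
    return MultiplayerGameBundle(
        strategies=("C", "D", "P"),
        tables={("C", "D"): cd, ("C", "P"): cp, ("D", "P"): dp},
    )


# -- dispatch helpers used by the chain/sweep layers -------------------


def n_strategies(game) -> int:
    """Number of strategies of any supported game object."""
    if isinstance(game, MatrixGame):
        return game.n
    if isinstance(game, MultiplayerPayoffTable):
        return 2
    if isinstance(game, MultiplayerGameBundle):
        return game.n
    raise TypeError(f"unsupported game type {type(game).__name__}")


def pairwise_profile(game, A: int, B: int, N: int) -> PairwiseProfile:
    """Invasion profile of strategy index ``A`` against ``B`` for any
    supported game object."""
    if isinstance(game, MatrixGame):
        return matrix_pair_profile(game, A, B, N)
    if isinstance(game, MultiplayerPayoffTable):
        if {A, B} != {0, 1}:
            raise InvalidPairError("a payoff table has strategies 0 (A) and 1 (B)")
        prof = multiplayer_pair_profile(game, N)
        return prof if A == 0 else prof.mirror()
    if isinstance(game, MultiplayerGameBundle):
        return game.pair_profile(A, B, N)
    raise TypeError(f"unsupported game type {type(game).__name__}")
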