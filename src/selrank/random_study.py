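"""Monte Carlo studies of rank changes in random two-player games.

Payoff matrices with i.i.d. Uniform(0,1) or standard Gaussian entries
are swept over a selection-intensity grid; for each sampled game the
number of pairwise rank changes and the number of changes in the
identity of the most abundant strategy are counted.  The study estimates
P(at least k rank changes) with binomial confidence intervals and the
expected total number of changes — the quantities that show how quickly
weak-selection predictions lose their validity as the number of
strategies grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .games import MatrixGame
from .rank_sweep import (
    DEFAULT_BETA_CAP,
    DEFAULT_BETA_MIN,
    DEFAULT_GRID_POINTS,
    BetaGrid,
    detect_crossings,
    study_beta_max,
    sweep,
)
from .update_rules import OverflowSignal, erf_rule, fermi_rule

__all__ = ["StudyConfig", "StudyResult", "sample_game", "run_study", "study_report"]

_DISTS = ("uniform01", "gaussian01")


@dataclass(frozen=True)
class StudyConfig:
    """Specification of one Monte Carlo study.

    ``dist`` is "uniform01" (payoffs i.i.d. on (0,1)) or "gaussian01"
    (mean 0, variance 1).  Each sample is driven by an independent
    sub-stream seeded by (seed, sample-index), so results do not depend
    on execution order.
    """

    n: int
    N: int = 100
    dist: str = "uniform01"
    samples: int = 2000
    rule: str = "fermi"
    beta: float = 1.0
    grid_points: int = DEFAULT_GRID_POINTS
    beta_min: float = DEFAULT_BETA_MIN
    beta_cap: float = DEFAULT_BETA_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two strategies")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if self.dist not in _DISTS:
            raise ValueError(f"dist must be one of {_DISTS}")
        if self.rule not in ("fermi", "erf"):
            raise ValueError("rule must be 'fermi' or 'erf'")

    def make_rule(self):
        return {"fermi": fermi_rule, "erf": erf_rule}[self.rule](self.beta)


@dataclass(frozen=True)
class StudyResult:
    """Aggregated study estimates.

    ``p_at_least[k]`` estimates P(>= k rank changes) with a Wilson 95%
    CI; ``top_p_at_least`` is the analogue for changes of the most
    abundant strategy; ``histogram[k]`` counts games with exactly k rank
    changes.  ``truncated`` lists samples whose grid had to stop below
    the cap because the rule overflowed (truncated, never dropped).
    """

    config: StudyConfig
    p_at_least: np.ndarray
    p_ci: np.ndarray
    top_p_at_least: np.ndarray
    top_ci: np.ndarray
    histogram: np.ndarray
    expected_total: float
    expected_total_se: float
    counts: np.ndarray = field(repr=False)
    top_counts: np.ndarray = field(repr=False)
    truncated: tuple[int, ...] = ()


def sample_game(dist: str, n: int, rng: np.random.Generator) -> MatrixGame:
    """Random n-strategy two-player game with i.i.d. payoff entries."""
    if dist == "uniform01":
        return MatrixGame(rng.uniform(0.0, 1.0, size=(n, n)))
    if dist == "gaussian01":
        return MatrixGame(rng.standard_normal((n, n)))
    raise ValueError(f"dist must be one of {_DISTS}")


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _tail_probability(counts: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    from statsmodels.stats.proportion import proportion_confint

    samples = counts.size
    p = np.empty(kmax + 1)
    ci = np.empty((kmax + 1, 2))
    for k in range(kmax + 1):
        hits = int(np.sum(counts >= k))
        p[k] = hits / samples
        ci[k] = proportion_confint(hits, samples, alpha=0.05, method="wilson")
    return p, ci


def run_study(config: StudyConfig) -> StudyResult:
    """Run the Monte Carlo study described by ``config``.

    Per sample: draw a game, adapt the grid top to the rule's overflow
    limit, sweep the stationary distribution, count crossings.
    Deterministic given the seed.
    """
    rule = config.make_rule()
    counts = np.zeros(config.samples, dtype=int)
    top_counts = np.zeros(config.samples, dtype=int)
    truncated: list[int] = []
    for idx in range(config.samples):
        rng = _sample_rng(config.seed, idx)
        game = sample_game(config.dist, config.n, rng)
        bmax = study_beta_max(game, rule, config.N, config.beta_cap)
        if bmax < config.beta_cap:
            truncated.append(idx)
        grid = BetaGrid.log(config.beta_min, bmax, config.grid_points)
        try:
            curve = sweep(game, rule, config.N, grid)
        except OverflowSignal:  # pragma: no cover - beta_max probe prevents this
            truncated.append(idx)
            continue
        rep = detect_crossings(curve)
        counts[idx] = rep.total_count
        top_counts[idx] = rep.top_changes

    kmax = max(1, int(counts.max()))  # always report k = 1 even for crossing-free studies
    p, ci = _tail_probability(counts, kmax)
    top_p, top_ci = _tail_probability(top_counts, kmax)
    hist = np.bincount(counts, minlength=kmax + 1)
    expected = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(config.samples)) if config.samples > 1 else 0.0
    return StudyResult(
        config=config,
        p_at_least=p,
        p_ci=ci,
        top_p_at_least=top_p,
        top_ci=top_ci,
        histogram=hist,
        expected_total=expected,
        expected_total_se=se,
        counts=counts,
        top_counts=top_counts,
        truncated=tuple(truncated),
    )


def study_report(result: StudyResult, format: str = "json", path=None):
    """Serialize a study: "json" (full summary) or "tsv" (tail
    probabilities vs k).  Returns the serialized text; writes it to
    ``path`` when given."""
    if format == "json":
        obj = {
            "config": asdict(result.config),
            "p_at_least": result.p_at_least.tolist(),
            "p_ci": result.p_ci.tolist(),
            "top_p_at_least": result.top_p_at_least.tolist(),
            "top_ci": result.top_ci.tolist(),
            "histogram": result.histogram.tolist(),
            "expected_total": result.expected_total,
            "expected_total_se": result.expected_total_se,
            "truncated_samples": list(result.truncated),
        }
        text = json.dumps(obj, indent=1)
    elif format == "tsv":
        kmax = result.p_at_least.size - 1
        df = pd.DataFrame(
            {
                "k": np.arange(kmax + 1),
                "p_at_least": result.p_at_least,
                "p_lo": result.p_ci[:, 0],
                "p_hi": result.p_ci[:, 1],
                "top_p_at_least": result.top_p_at_least,
                "top_lo": result.top_ci[:, 0],
                "top_hi": result.top_ci[:, 1],
                "histogram": result.histogram,
            }
        )
        text = df.to_csv(sep="\t", index=False)
    else:
        raise ValueError("format must be 'json' or 'tsv'")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_study_json(text: str) -> dict:
    """Re-parse a JSON study summary (round-trips all estimates)."""
    return json.loads(text)
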