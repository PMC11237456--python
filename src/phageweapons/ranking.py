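"""Random-phage ranking and rank-volatility analysis.

Is the "best" phage weapon the same under all invasion conditions?  To
answer this, random phages are drawn from the admissible trait ranges,
each is competed (as a lysogen) against the same phage-free control across
a grid of starting ratios, and the phages are ranked by PEI at every
ratio.  The number of phages whose rank changes between adjacent ratios
("rank volatility") measures how strongly the optimal-weapon ordering
depends on the starting conditions; regressing volatility on starting
ratio summarizes the trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, ParameterError
from .metrics import pei_frequency
from .params import (
    TRAIT_NAMES,
    TRAIT_RANGES,
    CommunityParams,
    LifeHistoryTraits,
    NutrientParams,
)
from .simulate import SolverConfig
from .sweeps import _WTCache

__all__ = [
    "sample_random_phages",
    "rank_phages",
    "rank_volatility",
    "volatility_regression",
    "run_rank_volatility_analysis",
    "RankTable",
    "VolatilitySeries",
    "RegressionFit",
    "RankVolatilityResult",
    "DEFAULT_RATIO_GRID",
]

#: Starting-ratio grid used for the volatility analysis: 11 evenly spaced
#: ratios spanning the invasion-to-defense range 0.01-0.99.
DEFAULT_RATIO_GRID = np.linspace(0.01, 0.99, 11)


def sample_random_phages(
    n: int,
    rng: np.random.Generator | int | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    log_traits: tuple[str, ...] = (),
) -> list[LifeHistoryTraits]:
    """Draw ``n`` random life-history trait sets.

    By default every trait is drawn uniformly on the linear scale over its
    (min, max) range.  Passing trait names in ``log_traits`` (e.g.
    ``("kappa", "alpha")``) switches those draws to log-uniform, which
    avoids the sample being dominated by the top decade of a wide range —
    but also concentrates the sample on weakly adsorbing, rarely inducing
    phages whose effectivities tie closely; see the volatility analysis
    notes for why the linear scheme is the default.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(rng)
    ranges = dict(TRAIT_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ParameterError(f"range for {name} has min > max")
    phages = []
    for _ in range(n):
        draw = {}
        for name in TRAIT_NAMES:
            lo, hi = ranges[name]
            if name in log_traits:
                draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                draw[name] = float(rng.uniform(lo, hi))
        phages.append(LifeHistoryTraits(**draw))
    return phages


@dataclass(frozen=True)
class RankTable:
    """PEI values and ranks per (phage, starting ratio); rank 1 = highest PEI."""

    phages: list[LifeHistoryTraits]
    f0_grid: np.ndarray
    pei: np.ndarray  # shape (n_phages, n_f0)
    ranks: np.ndarray  # int, same shape; each column a permutation of 1..n

    def __post_init__(self):
        n = len(self.phages)
        expected = set(range(1, n + 1))
        for j in range(self.ranks.shape[1]):
            if set(self.ranks[:, j].tolist()) != expected:
                raise ParameterError("ranks within each column must be a permutation of 1..n")

    def to_frame(self) -> pd.DataFrame:
        n, m = self.pei.shape
        return pd.DataFrame(
            {
                "phage": np.repeat(np.arange(n), m),
                "f0": np.tile(self.f0_grid, n),
                "pei": self.pei.ravel(),
                "rank": self.ranks.ravel(),
            }
        )


@dataclass(frozen=True)
class VolatilitySeries:
    """Counts of phages changing rank between adjacent starting ratios."""

    f0: np.ndarray  # ratio grid excluding the first point
    counts: np.ndarray  # int counts, same length
    set_id: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"set": self.set_id, "f0": self.f0, "rank_changes": self.counts})


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of rank volatility on starting ratio."""

    slope: float
    intercept: float
    r_squared: float
    t_statistic: float
    p_value: float
    df_resid: int
    n_points: int


def _rank_column(pei_col: np.ndarray) -> np.ndarray:
    # Descending PEI; ties broken by phage index (stable sort).
    order = np.argsort(-pei_col, kind="stable")
    ranks = np.empty(len(pei_col), dtype=int)
    ranks[order] = np.arange(1, len(pei_col) + 1)
    return ranks


def rank_phages(
    phages: list[LifeHistoryTraits],
    community: CommunityParams,
    f0_grid: np.ndarray | None = None,
    nutrient: NutrientParams | None = None,
    model_variant: str = "glv",
    total_N0: float = 1e6,
    horizon: float = 24.0,
    solver: SolverConfig | None = None,
    _cache: "_WTCache | None" = None,
) -> RankTable:
    """Compete every phage at every starting ratio and rank by PEI."""
    if len(phages) < 1:
        raise ParameterError("at least one phage is required")
    f0_grid = DEFAULT_RATIO_GRID if f0_grid is None else np.asarray(f0_grid, float)
    cache = _cache or _WTCache(
        community, nutrient, model_variant, solver, phages[0], total_N0, horizon
    )
    pei = np.empty((len(phages), len(f0_grid)))
    for j, f0 in enumerate(f0_grid):
        for i, traits in enumerate(phages):
            pei[i, j] = pei_frequency(cache.pair(float(f0), traits))
    ranks = np.column_stack([_rank_column(pei[:, j]) for j in range(len(f0_grid))])
    return RankTable(phages=list(phages), f0_grid=f0_grid, pei=pei, ranks=ranks)


def rank_volatility(table: RankTable) -> VolatilitySeries:
    """Count, at each ratio after the first, phages whose rank changed."""
    if len(table.f0_grid) < 2:
        raise ParameterError("at least two starting ratios are required")
    changed = table.ranks[:, 1:] != table.ranks[:, :-1]
    return VolatilitySeries(f0=table.f0_grid[1:], counts=changed.sum(axis=0))


def volatility_regression(series: list[VolatilitySeries]) -> RegressionFit:
    """Pooled OLS of rank-change counts on starting ratio."""
    x = np.concatenate([s.f0 for s in series])
    y = np.concatenate([s.counts for s in series]).astype(float)
    if len(x) < 3:
        raise FitError("need at least 3 points for the volatility regression")
    if np.ptp(x) == 0:
        raise FitError("zero variance in starting ratio")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        t_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        df_resid=int(fit.df_resid),
        n_points=len(x),
    )


@dataclass(frozen=True)
class RankVolatilityResult:
    series: list[VolatilitySeries]
    fit: RegressionFit

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.series], ignore_index=True)


def run_rank_volatility_analysis(
    community: CommunityParams,
    n_sets: int = 100,
    n_phages: int = 100,
    f0_grid: np.ndarray | None = None,
    seed: int | None = None,
    log_traits: tuple[str, ...] = (),
    nutrient: NutrientParams | None = None,
    model_variant: str = "glv",
    solver: SolverConfig | None = None,
) -> RankVolatilityResult:
    """Full pipeline: sample phage sets, rank, count changes, regress.

    The phage-free control runs depend only on the starting ratio and are
    shared across all sets and phages.
    """
    f0_grid = DEFAULT_RATIO_GRID if f0_grid is None else np.asarray(f0_grid, float)
    rng = np.random.default_rng(seed)
    cache: _WTCache | None = None
    series = []
    for set_id in range(n_sets):
        phages = sample_random_phages(n_phages, rng=rng, log_traits=log_traits)
        if cache is None:
            cache = _WTCache(community, nutrient, model_variant, solver, phages[0], 1e6, 24.0)
        table = rank_phages(
            phages, community, f0_grid, nutrient, model_variant, solver=solver, _cache=cache
        )
        vol = rank_volatility(table)
        series.append(VolatilitySeries(f0=vol.f0, counts=vol.counts, set_id=set_id))
    return RankVolatilityResult(series=series, fit=volatility_regression(series))
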