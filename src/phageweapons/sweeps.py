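"""Parameter-sweep grids of phage effectivity.

Two families of heatmap are produced: life-history trait versus starting
frequency (which trait values make a phage a useful weapon, and under what
invasion conditions), and trait versus induction rate at a fixed starting
frequency (which traits can compensate for the cost of a high induction
rate).  A helper predicts PEI-versus-frequency curves for two concrete
phage parameterizations, mirroring head-to-head experimental competitions.

Each grid cell is an independent paired competition; the phage-free
control run depends only on the starting frequency, so it is computed once
per frequency column and shared across cells (the result is identical to
running every pair from scratch because the integration is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .metrics import pei_frequency, pei_log_fold_change, pei_relative_fitness
from .params import (
    LOG_SCALE_TRAITS,
    TRAIT_NAMES,
    TRAIT_RANGES,
    CommunityParams,
    LifeHistoryTraits,
    NutrientParams,
)
from .simulate import CompetitionSetup, PairedOutcome, SolverConfig, integrate

__all__ = [
    "PEIGrid",
    "trait_grid",
    "frequency_grid",
    "sweep_trait_vs_frequency",
    "sweep_trait_vs_induction",
    "predict_experimental_pei",
]

METRICS = ("freq", "relfit", "logfold")


def _metric_value(pair: PairedOutcome, metric: str) -> float:
    if metric == "freq":
        return pei_frequency(pair)
    if metric == "relfit":
        return pei_relative_fitness(pair).v
    if metric == "logfold":
        return pei_log_fold_change(pair)
    raise ParameterError(f"unknown metric {metric!r}; expected one of {METRICS}")


def trait_grid(name: str, n: int = 25) -> np.ndarray:
    """Default grid over a trait's admissible range.

    Induction and absorption rates span four or more orders of magnitude,
    so their grids are log-spaced; the remaining traits get linear grids.
    """
    if name not in TRAIT_RANGES:
        raise ParameterError(f"unknown trait {name!r}")
    lo, hi = TRAIT_RANGES[name]
    if name in LOG_SCALE_TRAITS:
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


def frequency_grid(n: int = 25, lo: float = 0.01) -> np.ndarray:
    """Log-symmetric starting-frequency grid on [lo, 1 - lo].

    Points are geometrically spaced towards both endpoints so that the
    invasion (rare-lysogen) and defense (common-lysogen) regimes are both
    resolved.
    """
    if not 0 < lo < 0.5:
        raise ParameterError("lo must be in (0, 0.5)")
    lower = np.geomspace(lo, 0.5, n // 2 + 1)
    if n % 2 == 1:
        upper = 1.0 - lower[:-1][::-1]
        return np.concatenate([lower, upper])
    lower = lower[:-1]
    return np.concatenate([lower, 1.0 - lower[::-1]])


@dataclass(frozen=True)
class PEIGrid:
    """PEI evaluated over a 2-D parameter grid."""

    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    values: np.ndarray  # shape (len(y_values), len(x_values))
    baseline: LifeHistoryTraits
    community: CommunityParams
    metric: str

    def __post_init__(self):
        if self.values.shape != (len(self.y_values), len(self.x_values)):
            raise ParameterError("grid dimensions do not match values array")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("grid contains non-finite cells")

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with one row per cell."""
        ys, xs = np.meshgrid(self.y_values, self.x_values, indexing="ij")
        return pd.DataFrame(
            {
                self.x_name: xs.ravel(),
                self.y_name: ys.ravel(),
                "pei": self.values.ravel(),
                "metric": self.metric,
            }
        )

    def sign_changes(self) -> pd.DataFrame:
        """Zero-contour crossings along each column (fixed x, increasing y).

        Returns one row per sign change with the bracketing y values,
        locating the PEI = 0 contour of the heatmap.
        """
        rows = []
        for j, x in enumerate(self.x_values):
            col = self.values[:, j]
            sign = np.sign(col)
            flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
            for i in flips:
                rows.append(
                    {
                        self.x_name: x,
                        "y_below": self.y_values[i],
                        "y_above": self.y_values[i + 1],
                        "direction": "neg_to_pos" if col[i] < 0 else "pos_to_neg",
                    }
                )
        return pd.DataFrame(rows, columns=[self.x_name, "y_below", "y_above", "direction"])


class _WTCache:
    """Phage-free control runs keyed by starting frequency."""

    def __init__(self, community, nutrient, variant, solver, traits, total_N0, horizon):
        self.community = community
        self.nutrient = nutrient
        self.variant = variant
        self.solver = solver
        self.traits = traits
        self.total_N0 = total_N0
        self.horizon = horizon
        self._runs: dict[float, object] = {}

    def setup(self, f0: float, lysogen: bool) -> CompetitionSetup:
        return CompetitionSetup(
            focal_fraction=f0,
            total_N0=self.total_N0,
            focal_is_lysogen=lysogen,
            horizon=self.horizon,
            model_variant=self.variant,
        )

    def wt(self, f0: float):
        if f0 not in self._runs:
            self._runs[f0] = integrate(
                self.setup(f0, lysogen=False), self.traits, self.community,
                self.nutrient, solver=self.solver,
            )
        return self._runs[f0]

    def pair(self, f0: float, traits, novel_traits=None) -> PairedOutcome:
        lys = integrate(
            self.setup(f0, lysogen=True), traits, self.community,
            self.nutrient, novel_traits, self.solver,
        )
        return PairedOutcome(lysogen_run=lys, wt_run=self.wt(f0))


def sweep_trait_vs_frequency(
    trait_name: str,
    baseline: LifeHistoryTraits,
    community: CommunityParams,
    trait_values: np.ndarray | None = None,
    f0_grid: np.ndarray | None = None,
    metric: str = "freq",
    nutrient: NutrientParams | None = None,
    model_variant: str = "glv",
    total_N0: float = 1e6,
    horizon: float = 24.0,
    solver: SolverConfig | None = None,
) -> PEIGrid:
    """PEI over (trait value x starting frequency)."""
    if trait_name not in TRAIT_NAMES:
        raise ParameterError(f"unknown trait {trait_name!r}")
    trait_values = trait_grid(trait_name) if trait_values is None else np.asarray(trait_values, float)
    f0_grid = frequency_grid() if f0_grid is None else np.asarray(f0_grid, float)
    lo, hi = TRAIT_RANGES[trait_name]
    if np.any(trait_values < lo) or np.any(trait_values > hi):
        raise ParameterError(f"{trait_name} grid outside admissible range [{lo}, {hi}]")

    cache = _WTCache(community, nutrient, model_variant, solver, baseline, total_N0, horizon)
    values = np.empty((len(trait_values), len(f0_grid)))
    for j, f0 in enumerate(f0_grid):
        for i, tv in enumerate(trait_values):
            pair = cache.pair(float(f0), baseline.with_trait(trait_name, tv))
            values[i, j] = _metric_value(pair, metric)
    return PEIGrid(
        x_name="f0", x_values=f0_grid, y_name=trait_name, y_values=trait_values,
        values=values, baseline=baseline, community=community, metric=metric,
    )


def sweep_trait_vs_induction(
    trait_name: str,
    baseline: LifeHistoryTraits,
    community: CommunityParams,
    trait_values: np.ndarray | None = None,
    kappa_grid: np.ndarray | None = None,
    f0: float = 0.1,
    metric: str = "freq",
    nutrient: NutrientParams | None = None,
    model_variant: str = "glv",
    total_N0: float = 1e6,
    horizon: float = 24.0,
    solver: SolverConfig | None = None,
) -> PEIGrid:
    """PEI over (trait value x focal induction rate) at a fixed frequency.

    ``trait_name`` may also be ``"novel_kappa"``, in which case the y-axis
    varies the induction rate of the *novel* lysogens formed during the
    competition while the focal induction rate runs along the x-axis — the
    scenario of background strains whose fresh prophages induce faster
    than the focal strain's own.
    """
    novel_axis = trait_name == "novel_kappa"
    base_trait = "kappa" if novel_axis else trait_name
    if base_trait not in TRAIT_NAMES:
        raise ParameterError(f"unknown trait {trait_name!r}")
    trait_values = trait_grid(base_trait) if trait_values is None else np.asarray(trait_values, float)
    kappa_grid = trait_grid("kappa") if kappa_grid is None else np.asarray(kappa_grid, float)

    cache = _WTCache(community, nutrient, model_variant, solver, baseline, total_N0, horizon)
    values = np.empty((len(trait_values), len(kappa_grid)))
    for j, kap in enumerate(kappa_grid):
        focal = baseline.with_trait("kappa", kap)
        for i, tv in enumerate(trait_values):
            if novel_axis:
                traits, novel = focal, focal.with_trait("kappa", tv)
            else:
                traits, novel = focal.with_trait(trait_name, tv), None
            pair = cache.pair(float(f0), traits, novel)
            values[i, j] = _metric_value(pair, metric)
    return PEIGrid(
        x_name="kappa", x_values=kappa_grid, y_name=trait_name, y_values=trait_values,
        values=values, baseline=baseline, community=community, metric=metric,
    )


#: Starting frequencies used in the head-to-head experimental competitions.
EXPERIMENT_F0_GRID = np.array([0.01, 0.1, 0.5, 0.9, 0.99])


def predict_experimental_pei(
    phage_a: LifeHistoryTraits,
    phage_b: LifeHistoryTraits,
    community: CommunityParams,
    f0_grid: np.ndarray | None = None,
    labels: tuple[str, str] = ("phi2", "phi4"),
    metric: str = "freq",
    nutrient: NutrientParams | None = None,
    model_variant: str = "glv",
    solver: SolverConfig | None = None,
) -> pd.DataFrame:
    """Predicted PEI-versus-frequency curves for two phages.

    Returns a tidy frame with columns ``phage``, ``f0``, ``pei``.
    """
    f0_grid = EXPERIMENT_F0_GRID if f0_grid is None else np.asarray(f0_grid, float)
    cache = _WTCache(community, nutrient, model_variant, solver, phage_a, 1e6, 24.0)
    rows = []
    for label, traits in zip(labels, (phage_a, phage_b)):
        for f0 in f0_grid:
            pair = cache.pair(float(f0), traits)
            rows.append({"phage": label, "f0": float(f0), "pei": _metric_value(pair, metric)})
    return pd.DataFrame(rows)
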