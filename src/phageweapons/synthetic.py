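"""Synthetic assay counts and competition observations.

These generators emulate the measurement layer of the wet-lab pipeline so
that every analysis stage can be exercised end to end without laboratory
data: plate-assay counts whose noise-free estimator outputs equal a known
set of life-history traits, and competition observations (flow-cytometry
strain counts plus plate-reader density curves) drawn from simulated
trajectories.

Observation models
------------------
* Plate and fluorescence assays: the *response* measurement of each assay
  (the final phage titre, the background-subtracted fluorescence signal,
  the colony count on the phage-embedded lawn) carries mean-one
  multiplicative log-normal noise with a configurable coefficient of
  variation; the controlled inocula and phage-free reference counts are
  treated as exact design constants.  Because every estimator is linear in
  its single noisy response, the estimators remain unbiased under this
  model.
* Flow cytometry: focal and background counts are a binomial split of a
  fixed number of analyzed cells at the model's focal frequency.
* Density curves: readings proportional to total bacterial abundance with
  additive Gaussian noise (no optical-density calibration curve is
  applied, since only relative patterns are compared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import FitError, GeneratorError
from .life_history import (
    ABSORPTION_INCUBATION_H,
    AssayCounts,
    absorption_rate,
    burst_size,
    degradation_rate,
    induction_rate,
    probability_of_lysis,
)
from .metrics import focal_frequency
from .params import CommunityParams, LifeHistoryTraits, NutrientParams
from .simulate import CompetitionSetup, SolverConfig, Trajectory, integrate

__all__ = [
    "AssayPanel",
    "generate_assay_counts",
    "ObservedCompetition",
    "generate_competition_observations",
    "measured_pei",
    "density_table",
    "fit_density_model",
    "DensityModelFit",
    "DEFAULT_RATIOS",
]

# Assay design constants (titres per mL), mirroring typical inocula.
PFU_INOCULUM = 1e4
CFU_INOCULUM = 1e7
CELLS_LYSED = 1e4
LYSATE_TITRE = 1e8
CONTROL_COLONIES = 1000.0
DEGRADATION_HOURS = 24.0

#: Focal starting fractions of the competition-experiment design
#: (100:0, 99:1, 9:1, 1:1, 1:9, 1:99 focal:background).
DEFAULT_RATIOS = (1.0, 0.99, 0.9, 0.5, 0.1, 0.01)


def _noise_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative log-normal factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


@dataclass(frozen=True)
class AssayPanel:
    """One synthetic replicate of all five trait assays."""

    absorption: AssayCounts
    burst: AssayCounts
    degradation: AssayCounts
    induction: AssayCounts
    lysis: AssayCounts
    true_traits: LifeHistoryTraits
    noise_cv: float

    def estimate(self) -> dict[str, float]:
        """Apply each estimator under the conventions the generator encodes.

        Degradation uses the per-capita (relative) mode and probability of
        lysis the literal ratio, matching how the panel was constructed.
        """
        return {
            "alpha": absorption_rate(self.absorption),
            "beta": burst_size(self.burst),
            "delta": degradation_rate(self.degradation, relative=True),
            "kappa": induction_rate(self.induction),
            "pi": probability_of_lysis(self.lysis, mode="literal").value,
        }


def generate_assay_counts(
    true_traits: LifeHistoryTraits,
    noise_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> AssayPanel:
    """Synthesize assay counts whose noise-free estimates equal ``true_traits``.

    Each assay formula is inverted at the shipped design constants and the
    response measurement is then perturbed multiplicatively.  Traits
    outside the invertible domain of their assay design (absorption rate
    above ``6e-7`` per cell-hour, per-capita degradation above ``1/24``
    per hour, probability of lysis above 1) raise ``GeneratorError``.
    """
    if noise_cv < 0:
        raise GeneratorError("noise_cv must be >= 0")
    rng = np.random.default_rng(rng)
    tr = true_traits

    absorbed = tr.alpha * ABSORPTION_INCUBATION_H * CFU_INOCULUM  # fraction of virions lost
    if absorbed > 1:
        raise GeneratorError(
            "absorption rate too large for the assay design (all virions absorbed)"
        )
    decayed = tr.delta * DEGRADATION_HOURS  # fraction of the lysate titre lost
    if decayed > 1:
        raise GeneratorError(
            "degradation rate too large for the assay design (titre would go negative)"
        )

    absorption = AssayCounts(
        initial_pfu=PFU_INOCULUM,
        initial_cfu=CFU_INOCULUM,
        final_pfu=PFU_INOCULUM * (1.0 - absorbed) * _noise_factor(rng, noise_cv),
        elapsed=ABSORPTION_INCUBATION_H,
    )
    burst = AssayCounts(
        initial_pfu=PFU_INOCULUM,
        initial_cfu=CFU_INOCULUM,
        final_cfu=CFU_INOCULUM - CELLS_LYSED,
        final_pfu=(PFU_INOCULUM + tr.beta * CELLS_LYSED) * _noise_factor(rng, noise_cv),
    )
    degradation = AssayCounts(
        initial_pfu=LYSATE_TITRE,
        final_pfu=LYSATE_TITRE * (1.0 - decayed) * _noise_factor(rng, noise_cv),
        elapsed=DEGRADATION_HOURS,
    )
    # Background-subtracted fluorescence: the 5-h reference is zero and the
    # 10-h signal encodes the lysis-proxy slope.
    induction = AssayCounts(
        emission_t5=0.0,
        emission_t10=5.0 * tr.kappa * _noise_factor(rng, noise_cv),
    )
    lysis = AssayCounts(
        cfu_without_phage=CONTROL_COLONIES,
        cfu_with_phage=tr.pi * CONTROL_COLONIES * _noise_factor(rng, noise_cv),
    )
    return AssayPanel(
        absorption=absorption, burst=burst, degradation=degradation,
        induction=induction, lysis=lysis, true_traits=true_traits, noise_cv=noise_cv,
    )


@dataclass(frozen=True)
class ObservedCompetition:
    """Flow-count pairs and density curves for one replicate of a strain."""

    ratios: np.ndarray
    initial_focal: np.ndarray
    initial_background: np.ndarray
    final_focal: np.ndarray
    final_background: np.ndarray
    times: np.ndarray
    density: np.ndarray  # shape (n_ratios, n_times)
    lysogen: bool
    replicate: int = 0

    def initial_fraction(self) -> np.ndarray:
        return self.initial_focal / (self.initial_focal + self.initial_background)

    def final_fraction(self) -> np.ndarray:
        return self.final_focal / (self.final_focal + self.final_background)

    def final_density(self) -> np.ndarray:
        return self.density[:, -1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy density curves: one row per ratio x time."""
        n_r, n_t = self.density.shape
        return pd.DataFrame(
            {
                "ratio": np.repeat(self.ratios, n_t),
                "time": np.tile(self.times, n_r),
                "density": self.density.ravel(),
                "replicate": self.replicate,
            }
        )


def generate_competition_observations(
    focal_traits: LifeHistoryTraits,
    community: CommunityParams,
    nutrient: NutrientParams | None = None,
    model_variant: str = "glv",
    lysogen: bool = True,
    ratios=DEFAULT_RATIOS,
    flow_depth: int = 10_000,
    od_noise: float = 0.0,
    replicate: int = 0,
    rng: np.random.Generator | int | None = None,
    solver: SolverConfig | None = None,
    _trajectories: dict | None = None,
) -> ObservedCompetition:
    """Simulate competitions and observe them through the instrument models.

    ``flow_depth`` is the number of labelled cells analyzed per
    flow-cytometry sample; ``od_noise`` the additive Gaussian s.d. of the
    density readings (on the model's abundance scale).  Passing a dict as
    ``_trajectories`` memoizes model runs across replicates, which share
    trajectories and differ only in observation noise.
    """
    if flow_depth < 1:
        raise GeneratorError("flow_depth must be >= 1")
    rng = np.random.default_rng(rng)
    ratios = np.asarray(ratios, dtype=float)
    cadence_times = np.arange(0.0, 24.0 + 1e-9, 0.5)

    init_f = np.empty(len(ratios), dtype=int)
    final_f = np.empty(len(ratios), dtype=int)
    density = np.empty((len(ratios), len(cadence_times)))
    for i, f0 in enumerate(ratios):
        key = (float(f0), lysogen)
        traj: Trajectory | None = None if _trajectories is None else _trajectories.get(key)
        if traj is None:
            setup = CompetitionSetup(
                focal_fraction=float(f0), focal_is_lysogen=lysogen,
                model_variant=model_variant,
            )
            traj = integrate(setup, focal_traits, community, nutrient, solver=solver)
            if _trajectories is not None:
                _trajectories[key] = traj
        init_f[i] = rng.binomial(flow_depth, f0)
        final_f[i] = rng.binomial(flow_depth, focal_frequency(traj.final_state))
        total = traj.states[:, :3].sum(axis=1) + traj.states[:, 4:6].sum(axis=1)
        sampled = np.interp(cadence_times, traj.times, total)
        density[i] = sampled + rng.normal(0.0, od_noise, size=len(cadence_times)) if od_noise else sampled

    return ObservedCompetition(
        ratios=ratios,
        initial_focal=init_f,
        initial_background=flow_depth - init_f,
        final_focal=final_f,
        final_background=flow_depth - final_f,
        times=cadence_times,
        density=density,
        lysogen=lysogen,
        replicate=replicate,
    )


def measured_pei(obs_lysogen: ObservedCompetition, obs_control: ObservedCompetition) -> np.ndarray:
    """Per-ratio PEI computed from observed (flow-count) final fractions."""
    if not np.array_equal(obs_lysogen.ratios, obs_control.ratios):
        raise GeneratorError("lysogen and control observations must share ratios")
    return obs_lysogen.final_fraction() - obs_control.final_fraction()


def density_table(obs_by_strain: dict[str, list[ObservedCompetition]]) -> pd.DataFrame:
    """Stack final densities into a (strain, ratio, replicate) table."""
    rows = []
    for strain, obs_list in obs_by_strain.items():
        for obs in obs_list:
            for ratio, dens in zip(obs.ratios, obs.final_density()):
                rows.append(
                    {"strain": strain, "ratio": float(ratio),
                     "replicate": obs.replicate, "final_density": float(dens)}
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DensityModelFit:
    """OLS fit of final density on strain, starting ratio, and their interaction."""

    coefficients: pd.Series
    interaction_f: float
    interaction_p: float
    df_interaction: int
    df_resid: int
    n_obs: int


def fit_density_model(data: pd.DataFrame | dict) -> DensityModelFit:
    """Fit ``final_density ~ strain * ratio`` by ordinary least squares.

    ``data`` is either a tidy frame with columns ``strain``, ``ratio``,
    ``final_density`` (one row per replicate) or a dict of per-strain
    observation lists as produced by the generators.  The interaction F
    statistic tests whether the density-versus-ratio slope differs between
    strains.  Requires >= 2 strains, >= 2 ratios, and >= 2 replicates in
    every (strain, ratio) cell.
    """
    if isinstance(data, dict):
        data = density_table(data)
    required = {"strain", "ratio", "final_density"}
    if not required.issubset(data.columns):
        raise FitError(f"data must have columns {sorted(required)}")
    if data["strain"].nunique() < 2:
        raise FitError("need at least 2 strains")
    if data["ratio"].nunique() < 2:
        raise FitError("need at least 2 ratios")
    cell_counts = data.groupby(["strain", "ratio"]).size()
    if cell_counts.min() < 2:
        raise FitError("need at least 2 replicates per (strain, ratio) cell")

    fit = smf.ols("final_density ~ strain * ratio", data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise FitError("design matrix is rank deficient")
    anova = sm.stats.anova_lm(fit, typ=2)
    row = anova.loc["strain:ratio"]
    return DensityModelFit(
        coefficients=fit.params,
        interaction_f=float(row["F"]),
        interaction_p=float(row["PR(>F)"]),
        df_interaction=int(row["df"]),
        df_resid=int(fit.df_resid),
        n_obs=int(fit.nobs),
    )
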