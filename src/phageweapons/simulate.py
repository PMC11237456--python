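"""Initial conditions, ODE integration, and matched lysogen/control runs.

A competition starts from a total bacterial population split between the
focal and background strains at a chosen focal fraction, and is integrated
for a fixed horizon (24 h of batch culture by default).  The phage-free
control ("WT") run solves the *same* ODE system with the induction rate
forced to zero and no initial virions, so both members of a pair share
identical numerics and output grids; any difference between the runs is
attributable to phage processes alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import odeint

from . import _kernels
from .errors import IntegrationError, ParameterError
from .model import ModelState, STATE_FIELDS, glv_phage_rhs
from .model import nutrient_rhs as _nutrient_rhs_public
from .params import CommunityParams, LifeHistoryTraits, NutrientParams

__all__ = [
    "SolverConfig",
    "CompetitionSetup",
    "Trajectory",
    "PairedOutcome",
    "initial_state",
    "integrate",
    "run_competition_pair",
]

MODEL_VARIANTS = ("glv", "nutrient")


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive-step solver settings.

    ``n_points`` sets the evenly spaced output grid (241 points over 24 h
    gives 0.1-h resolution, finer than the 30-min cadence of plate-reader
    density curves).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    n_points: int = 241
    max_steps: int = 100_000

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ParameterError("solver tolerances must be > 0")
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")


@dataclass(frozen=True)
class CompetitionSetup:
    """Initial conditions and scope of a single competition run."""

    focal_fraction: float
    total_N0: float = 1e6
    focal_is_lysogen: bool = True
    horizon: float = 24.0
    model_variant: str = "glv"
    initial_P: float = 0.0

    def __post_init__(self):
        # Endpoint fractions (0 and 1) are permitted for control/monoculture runs.
        if not 0.0 <= self.focal_fraction <= 1.0:
            raise ParameterError("focal_fraction must be in [0, 1]")
        if self.total_N0 <= 0:
            raise ParameterError("total_N0 must be > 0")
        if self.horizon <= 0:
            raise ParameterError("horizon must be > 0")
        if self.model_variant not in MODEL_VARIANTS:
            raise ParameterError(f"model_variant must be one of {MODEL_VARIANTS}")
        if self.initial_P < 0:
            raise ParameterError("initial_P must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """An integrated run: sample times, states, and full provenance."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 6 or 7)
    setup: CompetitionSetup
    focal_traits: LifeHistoryTraits
    community: CommunityParams
    nutrient: NutrientParams | None = None
    novel_traits: LifeHistoryTraits | None = None

    @property
    def final_state(self) -> ModelState:
        return ModelState.from_array(self.states[-1])

    @property
    def initial(self) -> ModelState:
        return ModelState.from_array(self.states[0])

    def compartment(self, name: str) -> np.ndarray:
        """Time series of one compartment by name (F, B, N, P, Btilde, Ftilde, R)."""
        names = STATE_FIELDS + (("R",) if self.states.shape[1] == 7 else ())
        return self.states[:, names.index(name)]

    def to_frame(self, run_label: str = ""):
        """Tidy long-format export: one row per time x compartment."""
        import pandas as pd

        names = STATE_FIELDS + (("R",) if self.states.shape[1] == 7 else ())
        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, len(names)),
                "compartment": list(names) * n_t,
                "abundance": self.states.reshape(-1),
                "run": run_label,
            }
        )


@dataclass(frozen=True)
class PairedOutcome:
    """A lysogen run and its phage-free control from identical initial abundances."""

    lysogen_run: Trajectory
    wt_run: Trajectory

    def __post_init__(self):
        a, b = self.lysogen_run.setup, self.wt_run.setup
        same = (
            a.total_N0 == b.total_N0
            and a.focal_fraction == b.focal_fraction
            and a.horizon == b.horizon
            and a.model_variant == b.model_variant
        )
        if not same:
            raise ParameterError("paired runs must share N0, focal fraction, horizon and variant")


def initial_state(setup: CompetitionSetup, nutrient: NutrientParams | None = None) -> ModelState:
    """Initial compartment abundances for a competition run."""
    if setup.model_variant == "nutrient" and nutrient is None:
        raise ParameterError("nutrient parameters required for the nutrient variant")
    F0 = setup.focal_fraction * setup.total_N0
    B0 = (1.0 - setup.focal_fraction) * setup.total_N0
    P0 = setup.initial_P if setup.focal_is_lysogen else 0.0
    R0 = nutrient.R0 if setup.model_variant == "nutrient" else None
    return ModelState(F=F0, B=B0, N=0.0, P=P0, Btilde=0.0, Ftilde=0.0, R=R0)


def _kernel_args(
    setup: CompetitionSetup,
    focal_traits: LifeHistoryTraits,
    community: CommunityParams,
    nutrient: NutrientParams | None,
    novel_traits: LifeHistoryTraits | None,
):
    tr = focal_traits
    nt = tr if novel_traits is None else novel_traits
    kF, kN = (tr.kappa, nt.kappa) if setup.focal_is_lysogen else (0.0, 0.0)
    pool = 1.0 if community.include_induced_in_pool else 0.0
    mu = community.scalar_mu if setup.model_variant == "glv" else 0.0
    args = (community.r, mu, kF, kN, tr.lam, tr.alpha, tr.delta, tr.beta, tr.pi, pool)
    if setup.model_variant == "nutrient":
        args = args + (nutrient.k, nutrient.yield_per_cell)
        return _kernels.nutrient_rhs, _kernels.nutrient_jac, args
    return _kernels.glv_rhs, _kernels.glv_jac, args


def integrate(
    setup: CompetitionSetup,
    focal_traits: LifeHistoryTraits,
    community: CommunityParams,
    nutrient: NutrientParams | None = None,
    novel_traits: LifeHistoryTraits | None = None,
    solver: SolverConfig | None = None,
    y0: np.ndarray | ModelState | None = None,
) -> Trajectory:
    """Integrate one model variant over the horizon.

    When ``setup.focal_is_lysogen`` is false all phage processes are
    disabled (induction rates zeroed, no initial virions) but the full
    system is still integrated, so lysogen and control runs share numerics.
    ``y0`` overrides the standard initial condition (used for runs started
    from arbitrary states, e.g. single-burst scenarios).
    """
    solver = solver or SolverConfig()
    if setup.model_variant == "nutrient" and nutrient is None:
        raise ParameterError("nutrient parameters required for the nutrient variant")
    if y0 is None:
        y0_arr = initial_state(setup, nutrient).to_array()
    else:
        y0_arr = y0.to_array() if isinstance(y0, ModelState) else np.asarray(y0, dtype=float)

    times = np.linspace(0.0, setup.horizon, solver.n_points)

    use_kernel = setup.model_variant == "nutrient" or np.isscalar(community.mu) or (
        np.ptp(np.asarray(community.mu)) == 0
    )
    if use_kernel:
        rhs, jac, args = _kernel_args(setup, focal_traits, community, nutrient, novel_traits)
        out, info = odeint(
            rhs, y0_arr, times, args=args, Dfun=jac,
            rtol=solver.rtol, atol=solver.atol, mxstep=solver.max_steps,
            full_output=True, printmessg=False,
        )
    else:
        # General interaction-matrix path via the validated python RHS.
        out, info = _integrate_general(
            setup, focal_traits, community, nutrient, novel_traits, y0_arr, times, solver
        )

    if info["message"] != "Integration successful.":
        bad = int(np.argmax(~np.all(np.isfinite(out), axis=1))) if not np.all(
            np.isfinite(out)
        ) else len(times) - 1
        raise IntegrationError(
            f"ODE integration failed: {info['message']}", t_fail=float(times[bad])
        )
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite state encountered", t_fail=float(setup.horizon))

    # Honor non-negativity on reported samples; the solver itself is not clipped.
    out = np.clip(out, 0.0, None)
    out[0] = y0_arr  # the initial condition is exact by construction
    return Trajectory(
        times=times, states=out, setup=setup, focal_traits=focal_traits,
        community=community, nutrient=nutrient, novel_traits=novel_traits,
    )


def _integrate_general(setup, focal_traits, community, nutrient, novel_traits, y0_arr, times, solver):
    tr = focal_traits
    if not setup.focal_is_lysogen:
        tr = replace(tr, kappa=0.0)
        novel = replace(tr, kappa=0.0)
    else:
        novel = novel_traits

    def rhs(y, t):
        state = ModelState.from_array(np.clip(y, 0.0, None))
        if setup.model_variant == "nutrient":
            d = _nutrient_rhs_public(state, tr, community, nutrient, novel)
        else:
            d = glv_phage_rhs(state, tr, community, novel)
        return d.to_array()

    return odeint(
        rhs, y0_arr, times, rtol=solver.rtol, atol=solver.atol,
        mxstep=solver.max_steps, full_output=True, printmessg=False,
    )


def run_competition_pair(
    setup: CompetitionSetup,
    focal_traits: LifeHistoryTraits,
    community: CommunityParams,
    nutrient: NutrientParams | None = None,
    novel_traits: LifeHistoryTraits | None = None,
    solver: SolverConfig | None = None,
) -> PairedOutcome:
    """Run the lysogen and phage-free control competitions from one setup."""
    lys = integrate(
        replace(setup, focal_is_lysogen=True),
        focal_traits, community, nutrient, novel_traits, solver,
    )
    wt = integrate(
        replace(setup, focal_is_lysogen=False),
        focal_traits, community, nutrient, novel_traits, solver,
    )
    return PairedOutcome(lysogen_run=lys, wt_run=wt)
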