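"""State types and right-hand sides of the two competition-model variants.

The model tracks a focal bacterial strain F that may carry a temperate
phage, a susceptible background strain B, the novel lysogens N formed when
free phage lysogenize background cells, free phage virions P, and the
induced / lytically infected cell pools B~ ("Btilde") and F~ ("Ftilde")
that are committed to lysis.  Two variants of the growth law are provided:

* an interaction-based (generalized Lotka-Volterra) variant in which every
  living bacterial compartment grows at ``r + sum_j mu_ij x_j``, equivalent
  to logistic growth with the shared carrying capacity ``-r/mu`` when
  ``mu`` is a uniform scalar; and
* a resource-explicit variant in which growth is ``r * g`` with the
  saturating uptake function ``g = R / (R + k)`` and the nutrient R is
  depleted in proportion to the growth of F, B, and N.

Phage processes are identical in both variants: lysogens induce at rate
kappa into the committed pools, committed cells lyse at rate lam releasing
beta virions each, virions adsorb to susceptible cells at rate alpha
(lysing with probability pi, lysogenizing otherwise) and degrade at rate
delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidStateError, ParameterError
from .params import CommunityParams, LifeHistoryTraits, NutrientParams

__all__ = [
    "ModelState",
    "StateDerivative",
    "glv_phage_rhs",
    "nutrient_rhs",
    "carrying_capacity",
    "STATE_FIELDS",
]

#: Compartment names in solver ordering.
STATE_FIELDS = ("F", "B", "N", "P", "Btilde", "Ftilde")


@dataclass(frozen=True)
class ModelState:
    """Abundances of the model compartments.

    ``R`` (nutrient amount) is present only in the resource-explicit
    variant and is ``None`` otherwise.  All components must be finite and
    non-negative.
    """

    F: float
    B: float
    N: float
    P: float
    Btilde: float
    Ftilde: float
    R: float | None = None

    def __post_init__(self):
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidStateError(f"state component {name} = {v!r} must be finite and >= 0")
        if self.R is not None and (not math.isfinite(self.R) or self.R < 0):
            raise InvalidStateError(f"state component R = {self.R!r} must be finite and >= 0")

    @property
    def has_nutrient(self) -> bool:
        return self.R is not None

    def to_array(self) -> np.ndarray:
        vec = [getattr(self, name) for name in STATE_FIELDS]
        if self.R is not None:
            vec.append(self.R)
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape not in ((6,), (7,)):
            raise InvalidStateError(f"state vector must have 6 or 7 components, got {y.shape}")
        R = float(y[6]) if y.shape == (7,) else None
        return cls(*map(float, y[:6]), R=R)


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of each compartment (same ordering and units/hour)."""

    F: float
    B: float
    N: float
    P: float
    Btilde: float
    Ftilde: float
    R: float | None = None

    def to_array(self) -> np.ndarray:
        vec = [getattr(self, name) for name in STATE_FIELDS]
        if self.R is not None:
            vec.append(self.R)
        return np.asarray(vec, dtype=float)


def _growth_terms(y: np.ndarray, community: CommunityParams) -> np.ndarray:
    """Per-capita growth term ``r + sum_j mu_ij x_j`` for (F, B, N, B~, F~)."""
    bact = y[:3].tolist() + [y[4], y[5]]
    x = np.asarray(bact, dtype=float)
    if not community.include_induced_in_pool:
        x = x * np.array([1.0, 1.0, 1.0, 0.0, 0.0])
    if np.isscalar(community.mu):
        return community.r + community.mu * x.sum() * np.ones(5)
    return community.r + np.asarray(community.mu) @ x


def _check_state(state: ModelState, need_nutrient: bool) -> np.ndarray:
    y = state.to_array()
    if need_nutrient and not state.has_nutrient:
        raise InvalidStateError("this model variant requires a nutrient component R")
    return y


def glv_phage_rhs(
    state: ModelState,
    focal_traits: LifeHistoryTraits,
    community: CommunityParams,
    novel_traits: LifeHistoryTraits | None = None,
) -> StateDerivative:
    """Derivatives of the interaction-based (gLV) variant.

    ``novel_traits`` defaults to ``focal_traits``; supplying a different
    induction rate for the novel lysogens models background strains whose
    freshly acquired prophages induce at their own rate.  Phage kinetics
    (lysis rate, burst size, adsorption, degradation) always follow the
    focal phage, since every virion in the system descends from it.
    """
    y = _check_state(state, need_nutrient=False)
    nt = focal_traits if novel_traits is None else novel_traits
    F, B, N, P, Bt, Ft = y[:6]
    gF, gB, gN, _, _ = _growth_terms(y, community)
    tr = focal_traits
    aP = tr.alpha * P
    dF = F * (gF - tr.kappa)
    dB = B * (gB - aP)
    dN = B * aP * (1.0 - tr.pi) + N * (gN - nt.kappa)
    dP = tr.beta * tr.lam * (Bt + Ft) - aP * B - tr.delta * P
    dBt = nt.kappa * N + tr.alpha * tr.pi * B * P - tr.lam * Bt
    dFt = tr.kappa * F - tr.lam * Ft
    return StateDerivative(dF, dB, dN, dP, dBt, dFt)


def nutrient_rhs(
    state: ModelState,
    focal_traits: LifeHistoryTraits,
    community: CommunityParams,
    nutrient: NutrientParams,
    novel_traits: LifeHistoryTraits | None = None,
) -> StateDerivative:
    """Derivatives of the resource-explicit variant.

    Growth is ``r * g`` with ``g = R / (R + k)``; no pairwise interaction
    terms appear.  Nutrient depletion tracks the growth of the three
    replicating pools F, B, and N (committed cells no longer divide, so
    they consume nothing).
    """
    y = _check_state(state, need_nutrient=True)
    nt = focal_traits if novel_traits is None else novel_traits
    F, B, N, P, Bt, Ft, R = y
    g = R / (R + nutrient.k)
    rg = community.r * g
    tr = focal_traits
    aP = tr.alpha * P
    dF = F * (rg - tr.kappa)
    dB = B * (rg - aP)
    dN = B * aP * (1.0 - tr.pi) + N * (rg - nt.kappa)
    dP = tr.beta * tr.lam * (Bt + Ft) - aP * B - tr.delta * P
    dBt = nt.kappa * N + tr.alpha * tr.pi * B * P - tr.lam * Bt
    dFt = tr.kappa * F - tr.lam * Ft
    dR = -nutrient.yield_per_cell * rg * (F + B + N)
    return StateDerivative(dF, dB, dN, dP, dBt, dFt, dR)


def carrying_capacity(community: CommunityParams) -> float:
    """Single-strain fixed point ``-r/mu`` of the gLV variant with kappa = 0."""
    mu = community.scalar_mu
    if mu == 0:
        raise ParameterError("mu = 0: the community has no finite carrying capacity")
    return -community.r / mu
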