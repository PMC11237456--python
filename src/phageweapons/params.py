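"""Parameter types, trait ranges, and named parameter presets.

The model couples a temperate phage's six life-history traits to a small
bacterial community: a focal strain that may carry the phage as a prophage,
a susceptible background strain, and the novel lysogens formed when the
phage integrates into background cells.  Community-level growth is governed
by a shared intrinsic growth rate ``r`` and a competitive interaction
coefficient ``mu`` applied between every pair of living bacterial
compartments (a full interaction matrix is also accepted).

Three presets ship with the package:

``fixed``
    The baseline parameterization used for the trait sweeps.
``phi2`` / ``phi4``
    Parameterizations of two temperate phages isolated from the Liverpool
    epidemic strain of *Pseudomonas aeruginosa* (LESB58 Phi2 and Phi4),
    which differ only in their probability of lysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ParameterError

__all__ = [
    "LifeHistoryTraits",
    "CommunityParams",
    "NutrientParams",
    "TRAIT_RANGES",
    "LOG_SCALE_TRAITS",
    "TRAIT_NAMES",
    "load_preset",
    "load_config",
    "available_presets",
]

#: Trait names in canonical order.
TRAIT_NAMES = ("pi", "kappa", "lam", "alpha", "delta", "beta")

#: Admissible (min, max) range explored for each life-history trait.
TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "pi": (0.01, 0.99),
    "kappa": (1e-5, 0.9),
    "lam": (0.01, 1.0),
    "alpha": (1e-10, 1e-6),
    "delta": (1e-5, 0.9),
    "beta": (10.0, 1010.0),
}

#: Traits whose explored range spans several orders of magnitude; grids and
#: random draws over these are log-spaced by default.
LOG_SCALE_TRAITS = ("kappa", "alpha")


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class LifeHistoryTraits:
    """The six life-history traits of a temperate phage.

    Parameters
    ----------
    pi : float
        Probability that a new infection proceeds lytically (dimensionless,
        in [0, 1]); with probability ``1 - pi`` the infected cell becomes a
        novel lysogen.
    kappa : float
        Spontaneous induction rate of the prophage (per hour).
    lam : float
        Lysis rate of induced/lytically infected cells (per hour).
    alpha : float
        Absorption (adsorption) rate of free virions onto susceptible
        cells (per cell per hour).
    delta : float
        Degradation rate of free virions (per hour).
    beta : float
        Burst size: virions released per lysed cell (real-valued, >= 0).
    """

    pi: float
    kappa: float
    lam: float
    alpha: float
    delta: float
    beta: float

    def __post_init__(self):
        for name in TRAIT_NAMES:
            _check_finite(name, getattr(self, name))
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.pi > 1:
            raise ParameterError(f"pi must be in [0, 1], got {self.pi}")

    def with_trait(self, name: str, value: float) -> "LifeHistoryTraits":
        """Return a copy with one trait replaced."""
        if name not in TRAIT_NAMES:
            raise ParameterError(f"unknown trait {name!r}; expected one of {TRAIT_NAMES}")
        return replace(self, **{name: float(value)})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TRAIT_NAMES}


@dataclass(frozen=True)
class CommunityParams:
    """Shared ecological parameters of the bacterial community.

    ``mu`` may be a single scalar (the default, applied between every pair
    of living bacterial compartments including self) or a full 5x5 matrix
    over the compartments (F, B, N, B~, F~); matrix entries must be
    non-positive (competitive) and the matrix symmetric (reciprocal).

    ``include_induced_in_pool`` controls whether the induced compartments
    B~ and F~ count towards the competition sum.  Induced cells are living
    cells until they lyse, so they are included by default; excluding them
    reproduces a strictly pre-induction competition pool.
    """

    r: float = 0.9
    mu: float | np.ndarray = -4e-10
    include_induced_in_pool: bool = True

    def __post_init__(self):
        _check_finite("r", self.r)
        if self.r < 0:
            raise ParameterError("r must be >= 0")
        if np.isscalar(self.mu):
            if not math.isfinite(self.mu):
                raise ParameterError("mu must be finite")
            if self.mu > 0:
                raise ParameterError("mu must be <= 0 (competitive)")
        else:
            m = np.asarray(self.mu, dtype=float)
            if m.shape != (5, 5):
                raise ParameterError("matrix mu must be 5x5 over (F, B, N, B~, F~)")
            if not np.all(np.isfinite(m)):
                raise ParameterError("mu entries must be finite")
            if np.any(m > 0):
                raise ParameterError("mu entries must be <= 0 (competitive)")
            if not np.allclose(m, m.T):
                raise ParameterError("matrix mu must be symmetric (reciprocal)")
            object.__setattr__(self, "mu", m)

    @property
    def scalar_mu(self) -> float:
        """The shared interaction coefficient, when ``mu`` is uniform."""
        if np.isscalar(self.mu):
            return float(self.mu)
        m = np.asarray(self.mu)
        if np.ptp(m) == 0:
            return float(m.flat[0])
        raise ParameterError("mu is a non-uniform matrix; no single scalar value")


@dataclass(frozen=True)
class NutrientParams:
    """Parameters of the resource-explicit (Monod-type) model variant.

    Growth scales with the saturating uptake function g = R / (R + k).
    Defaults are chosen so that the nutrient model's yield-limited
    capacity ``R0 / yield_per_cell`` equals the logistic capacity ``-r/mu``
    of the interaction-based variant (2.25e9 cells with the shipped
    community parameters).
    """

    k: float = 1.125
    yield_per_cell: float = 5e-9
    R0: float = 11.25

    def __post_init__(self):
        for name in ("k", "yield_per_cell", "R0"):
            _check_finite(name, getattr(self, name))
        if self.k <= 0:
            raise ParameterError("k must be > 0")
        if self.yield_per_cell <= 0:
            raise ParameterError("yield_per_cell must be > 0")
        if self.R0 < 0:
            raise ParameterError("R0 must be >= 0")


def _parse_config(doc: Mapping) -> dict:
    out: dict = {}
    if "traits" in doc:
        t = dict(doc["traits"])
        out["traits"] = LifeHistoryTraits(**{k: float(v) for k, v in t.items()})
    if "community" in doc:
        c = dict(doc["community"])
        kwargs = {}
        if "r" in c:
            kwargs["r"] = float(c["r"])
        if "mu" in c:
            mu = c["mu"]
            kwargs["mu"] = np.asarray(mu, dtype=float) if isinstance(mu, list) else float(mu)
        if "include_induced_in_pool" in c:
            kwargs["include_induced_in_pool"] = bool(c["include_induced_in_pool"])
        out["community"] = CommunityParams(**kwargs)
    if "nutrient" in doc:
        n = dict(doc["nutrient"])
        if "yield" in n:  # accept the field's conventional name in config files
            n["yield_per_cell"] = n.pop("yield")
        out["nutrient"] = NutrientParams(**{k: float(v) for k, v in n.items()})
    return out


def load_config(path: str | Path) -> dict:
    """Read a parameter config file (YAML with traits/community/nutrient sections).

    Returns a dict with any of the keys ``traits``, ``community``,
    ``nutrient`` populated with validated parameter objects.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ParameterError(f"config file {path} does not contain a mapping")
    return _parse_config(doc)


def available_presets() -> list[str]:
    """Names of the parameter presets shipped with the package."""
    pkg = resources.files("phageweapons") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a shipped preset (``fixed``, ``phi2`` or ``phi4``) by name."""
    pkg = resources.files("phageweapons") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    return _parse_config(yaml.safe_load(text))
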