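"""Phage effectivity metrics and trajectory summaries.

The phage effectivity index (PEI) quantifies the advantage a focal strain
gains from carrying a temperate phage, by contrasting a competition run in
which the focal strain is a lysogen with a phage-free control started from
the same initial abundances.  Three variants are provided:

* ``pei_frequency`` — the difference in the focal strain's final frequency
  between the two runs (the headline index, bounded in [-1, 1]);
* ``pei_relative_fitness`` — the ratio of the Malthusian growth of the
  focal lineage to that of the background lineage in the lysogen run;
* ``pei_log_fold_change`` — the natural-log fold change of the focal
  lineage, contrasted between runs.

By the default counting convention the focal lineage is F + F~ and the
background lineage is B + B~ + N: induced cells remain living members of
their lineage until lysis, and novel lysogens descend from background
cells.  Passing ``include_induced=False`` restricts counting to the
uninduced compartments.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .errors import MetricError
from .model import ModelState
from .simulate import PairedOutcome, Trajectory

__all__ = [
    "focal_frequency",
    "pei_frequency",
    "pei_relative_fitness",
    "pei_log_fold_change",
    "phage_output",
    "final_total_density",
    "RelativeFitness",
    "PhageOutput",
]


def _focal_count(state: ModelState, include_induced: bool) -> float:
    return state.F + (state.Ftilde if include_induced else 0.0)


def _background_count(state: ModelState, include_induced: bool) -> float:
    return state.B + state.N + (state.Btilde if include_induced else 0.0)


def focal_frequency(state: ModelState, include_induced: bool = True) -> float:
    """Frequency of the focal lineage among all counted bacterial cells."""
    focal = _focal_count(state, include_induced)
    total = focal + _background_count(state, include_induced)
    if total <= 0:
        raise MetricError("all counted compartments are zero; frequency undefined")
    return focal / total


def pei_frequency(pair: PairedOutcome, include_induced: bool = True) -> float:
    """Frequency-difference PEI: final focal frequency with minus without phage."""
    f_lys = focal_frequency(pair.lysogen_run.final_state, include_induced)
    f_wt = focal_frequency(pair.wt_run.final_state, include_induced)
    return f_lys - f_wt


class RelativeFitness(NamedTuple):
    """Malthusian relative fitness of the focal vs background lineage.

    ``v`` is computed on the lysogen run; ``v_wt`` on the control run is
    carried along for reference (it is 1 for identical strain parameters).
    """

    v: float
    v_wt: float


def _malthusian_ratio(traj: Trajectory, include_induced: bool) -> float:
    s0, s1 = traj.initial, traj.final_state
    f0, f1 = _focal_count(s0, include_induced), _focal_count(s1, include_induced)
    b0, b1 = _background_count(s0, include_induced), _background_count(s1, include_induced)
    if min(f0, f1, b0, b1) <= 0:
        raise MetricError("relative fitness requires positive focal and background abundances")
    denom = math.log(b1 / b0)
    if denom == 0:
        raise MetricError("background lineage did not change; relative fitness undefined")
    return math.log(f1 / f0) / denom


def pei_relative_fitness(pair: PairedOutcome, include_induced: bool = True) -> RelativeFitness:
    """Relative fitness v = ln(F_end/F_0) / ln(BG_end/BG_0), per run."""
    return RelativeFitness(
        v=_malthusian_ratio(pair.lysogen_run, include_induced),
        v_wt=_malthusian_ratio(pair.wt_run, include_induced),
    )


def pei_log_fold_change(
    pair: PairedOutcome, include_induced: bool = True, contrast: bool = True
) -> float:
    """Natural-log fold change of the focal lineage.

    With ``contrast=True`` (default) the control run's fold change is
    subtracted, isolating the phage's contribution to the focal strain's
    average growth; ``contrast=False`` returns the raw lysogen-run value.
    """

    def lfc(traj: Trajectory) -> float:
        f0 = _focal_count(traj.initial, include_induced)
        f1 = _focal_count(traj.final_state, include_induced)
        if f0 <= 0 or f1 <= 0:
            raise MetricError("log fold change requires positive focal abundances")
        return math.log(f1 / f0)

    value = lfc(pair.lysogen_run)
    if contrast:
        value -= lfc(pair.wt_run)
    return value


class PhageOutput(NamedTuple):
    final_free: float
    cumulative_produced: float


def phage_output(traj: Trajectory) -> PhageOutput:
    """Final free virions and cumulative virion production of a run.

    Cumulative production integrates the lysis source term
    ``beta * lam * (B~ + F~)`` over the sampled trajectory by trapezoidal
    quadrature, so no extra ODE state is needed.
    """
    tr = traj.focal_traits
    committed = traj.compartment("Btilde") + traj.compartment("Ftilde")
    produced = float(np.trapezoid(tr.beta * tr.lam * committed, traj.times))
    return PhageOutput(final_free=float(traj.compartment("P")[-1]), cumulative_produced=produced)


def final_total_density(traj: Trajectory, include_induced: bool = True) -> float:
    """Total counted bacterial abundance at the end of the run."""
    s = traj.final_state
    return _focal_count(s, include_induced) + _background_count(s, include_induced)
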