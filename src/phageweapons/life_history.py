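"""Estimators of phage life-history traits from plate and plate-reader assays.

Each estimator turns the raw counts of one wet-lab assay into a trait
value:

* absorption rate from the loss of free virions after a 10-minute
  co-incubation with susceptible cells;
* burst size from the ratio of virions gained to cells lost over an
  infection cycle;
* degradation rate from the decay of a cell-free lysate over 24 h;
* induction rate (as a proxy) from the slope of a DNA-release
  (Sytox-type) fluorescence signal between 5 h and 10 h;
* probability of lysis from colony counts on phage-embedded versus
  phage-free lawns.

Counts are volumetric titres (PFU/mL, CFU/mL) or arbitrary fluorescence
units; only the fields an estimator uses need be present on the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .errors import EstimatorError

__all__ = [
    "AssayCounts",
    "absorption_rate",
    "burst_size",
    "degradation_rate",
    "induction_rate",
    "probability_of_lysis",
    "PoLEstimate",
]

#: Incubation time of the absorption assay, in hours (10 minutes).
ABSORPTION_INCUBATION_H = 1.0 / 6.0


@dataclass(frozen=True)
class AssayCounts:
    """Raw measurements from one assay replicate.

    Only the fields relevant to a given estimator need be present; all
    counts must be non-negative.
    """

    initial_pfu: float | None = None
    final_pfu: float | None = None
    initial_cfu: float | None = None
    final_cfu: float | None = None
    emission_t5: float | None = None
    emission_t10: float | None = None
    cfu_with_phage: float | None = None
    cfu_without_phage: float | None = None
    elapsed: float | None = None

    def __post_init__(self):
        for name in (
            "initial_pfu", "final_pfu", "initial_cfu", "final_cfu",
            "emission_t5", "emission_t10", "cfu_with_phage", "cfu_without_phage",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise EstimatorError(f"{name} must be >= 0, got {v}")

    def _require(self, *names: str):
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise EstimatorError(f"assay counts missing required fields: {missing}")


def absorption_rate(counts: AssayCounts, literal: bool = False) -> float:
    """Adsorption rate (per cell per hour) from free-virion loss.

    Default convention: ``|final PFU - initial PFU| / ((1/6) * initial PFU
    * initial CFU)`` — virion loss over the 10-minute incubation expressed
    as a magnitude, normalized by both inocula.  ``literal=True`` instead
    evaluates the signed expression with the bare constant 16 in the
    denominator, as the assay formula is sometimes typeset.
    """
    counts._require("initial_pfu", "final_pfu", "initial_cfu")
    if counts.initial_pfu <= 0 or counts.initial_cfu <= 0:
        raise EstimatorError("absorption rate requires positive initial PFU and CFU")
    diff = counts.final_pfu - counts.initial_pfu
    if literal:
        return diff / (16.0 * counts.initial_pfu * counts.initial_cfu)
    return abs(diff) / (ABSORPTION_INCUBATION_H * counts.initial_pfu * counts.initial_cfu)


def burst_size(counts: AssayCounts) -> float:
    """Virions produced per lysed cell: (PFU gained) / (CFU lost)."""
    counts._require("initial_pfu", "final_pfu", "initial_cfu", "final_cfu")
    cells_lost = counts.initial_cfu - counts.final_cfu
    if cells_lost <= 0:
        raise EstimatorError("burst size requires a net loss of cells (initial CFU > final CFU)")
    return (counts.final_pfu - counts.initial_pfu) / cells_lost


def degradation_rate(counts: AssayCounts, relative: bool = False) -> float:
    """Virion decay from a cell-free lysate incubated for 24 h (default).

    The default returns the absolute titre loss per hour,
    ``(PFU_t0 - PFU_tEnd) / elapsed``.  With ``relative=True`` the loss is
    additionally divided by the starting titre, giving the per-capita
    decay rate (per hour) that matches the model's delta dimensionally.
    A negative value (titre growth without cells) is returned with a
    warning rather than raising.
    """
    counts._require("initial_pfu", "final_pfu")
    elapsed = 24.0 if counts.elapsed is None else counts.elapsed
    if elapsed <= 0:
        raise EstimatorError("elapsed must be > 0")
    rate = (counts.initial_pfu - counts.final_pfu) / elapsed
    if relative:
        if counts.initial_pfu <= 0:
            raise EstimatorError("relative degradation rate requires positive initial PFU")
        rate /= counts.initial_pfu
    if rate < 0:
        warnings.warn("negative degradation rate: final titre exceeds initial", stacklevel=2)
    return rate


def induction_rate(counts: AssayCounts) -> float:
    """Spontaneous-lysis proxy: fluorescence emission slope between 5 and 10 h.

    Units are emission units per hour; the value orders strains by their
    spontaneous lysis but carries no absolute calibration to the model's
    kappa.
    """
    counts._require("emission_t5", "emission_t10")
    return (counts.emission_t10 - counts.emission_t5) / 5.0


class PoLEstimate(NamedTuple):
    """Probability-of-lysis estimate with its counting convention."""

    value: float
    mode: str


def probability_of_lysis(counts: AssayCounts, mode: str = "literal") -> PoLEstimate:
    """Probability of lysis from colony counts on phage-embedded lawns.

    ``mode="literal"`` (default) returns the ratio of colonies on the
    phage-embedded lawn to colonies on the phage-free control, the
    convention under which the shipped phage parameterizations were
    calibrated.  ``mode="complement"`` returns one minus that ratio — the
    survival-fraction reading, under which surviving colonies are the
    lysogenized (non-lysed) infections.
    """
    if mode not in ("literal", "complement"):
        raise EstimatorError(f"unknown mode {mode!r}; expected 'literal' or 'complement'")
    counts._require("cfu_with_phage", "cfu_without_phage")
    if counts.cfu_without_phage <= 0:
        raise EstimatorError("probability of lysis requires a positive control count")
    ratio = counts.cfu_with_phage / counts.cfu_without_phage
    return PoLEstimate(value=ratio if mode == "literal" else 1.0 - ratio, mode=mode)
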