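"""Dissimilarity response of a pairwise plant-soil feedback experiment.

A pairwise feedback experiment grows two plant species, A and B, in soil
cultivated by each species, giving four biomass means: ``A_a`` (species A in
A-cultivated soil), ``A_b`` (A in B-soil), ``B_a`` and ``B_b``. The
dissimilarity response is the difference of log biomass ratios across the two
soils,

    r = ln(A_a / B_a) - ln(A_b / B_b),

with the conspecific-soil performance of the "left" species in the numerator
of the left-hand ratio, so that positive ``r`` means the two species perform
better overall in conspecific soil (a net positive feedback). ``r = 0`` means
the two species respond proportionally identically to the two soil
communities; its magnitude does not depend on which species is labelled A.

The sampling variance of ``r`` follows from the first-order delta method on
the log scale: the variance of a log mean is approximately ``(SE/mean)**2``,
and the four means are independent, so

    var(r) = (se_Aa/A_a)**2 + (se_Ba/B_a)**2 + (se_Ab/A_b)**2 + (se_Bb/B_b)**2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

__all__ = [
    "FeedbackExperiment",
    "DissimilarityObservation",
    "InvalidExperimentError",
    "compute_r",
    "compute_r_variance",
    "orient_pair",
]

logger = logging.getLogger(__name__)


class InvalidExperimentError(ValueError):
    """A feedback experiment violates the positivity/finiteness contract."""


@dataclass(frozen=True)
class FeedbackExperiment:
    """One replicate pairwise feedback experiment.

    Biomass means must be strictly positive (they enter log ratios); standard
    errors must be non-negative and finite. ``soil_fraction`` is the
    proportion of live inoculum in the growth substrate and ``whole_soil``
    flags experiments that used the whole soil community rather than a
    fraction of it (e.g. only mycorrhizal fungi).
    """

    species_a_id: str
    species_b_id: str
    A_a: float
    A_b: float
    B_a: float
    B_b: float
    se_A_a: float = 0.0
    se_A_b: float = 0.0
    se_B_a: float = 0.0
    se_B_b: float = 0.0
    treatment_label: str = ""
    soil_fraction: float = 1.0
    whole_soil: bool = True

    def validate(self) -> None:
        for name in ("A_a", "A_b", "B_a", "B_b"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise InvalidExperimentError(
                    f"biomass mean {name}={value!r} must be strictly positive and finite"
                )
        for name in ("se_A_a", "se_A_b", "se_B_a", "se_B_b"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise InvalidExperimentError(
                    f"standard error {name}={value!r} must be non-negative and finite"
                )


@dataclass(frozen=True)
class DissimilarityObservation:
    """(r, var_r) for one replicate of a species pair.

    ``replicate_index`` starts at 1; ``pair_id`` references the SpeciesPair
    the observation belongs to.
    """

    r: float
    var_r: float
    pair_id: str
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValueError(f"r={self.r!r} must be finite")
        if not (self.var_r >= 0.0 and math.isfinite(self.var_r)):
            raise ValueError(f"var_r={self.var_r!r} must be non-negative and finite")
        if self.replicate_index < 1:
            raise ValueError("replicate_index starts at 1")


def compute_r(exp: FeedbackExperiment) -> float:
    """Dissimilarity response r = ln(A_a/B_a) - ln(A_b/B_b).

    Unitless; invariant to rescaling either species' biomasses by a common
    factor, and (by the algebraic identity ln(B_b/A_b) - ln(B_a/A_a) =
    ln(A_a/B_a) - ln(A_b/B_b)) invariant to swapping the species labels.
    """
    exp.validate()
    return math.log(exp.A_a / exp.B_a) - math.log(exp.A_b / exp.B_b)


def compute_r_variance(exp: FeedbackExperiment) -> float:
    """First-order delta-method sampling variance of r.

    Sums the squared relative standard errors of the four biomass means.
    Zero standard errors contribute zero variance: the observation is then
    taken at face value (logged as a warning, since real compilations with
    missing SEs understate uncertainty).
    """
    exp.validate()
    if (exp.se_A_a, exp.se_A_b, exp.se_B_a, exp.se_B_b) == (0.0, 0.0, 0.0, 0.0):
        logger.warning(
            "all standard errors are zero for pair (%s, %s); var(r)=0 assumed",
            exp.species_a_id,
            exp.species_b_id,
        )
    return (
        (exp.se_A_a / exp.A_a) ** 2
        + (exp.se_B_a / exp.B_a) ** 2
        + (exp.se_A_b / exp.A_b) ** 2
        + (exp.se_B_b / exp.B_b) ** 2
    )


def orient_pair(exp: FeedbackExperiment) -> FeedbackExperiment:
    """Return the experiment in the canonical species orientation.

    The canonical orientation sorts the two species labels, so that any
    relabelling of the same physical experiment maps to one representative.
    Under the conspecific-numerator convention the value of r is already
    invariant to swapping species (sign included), so this only fixes which
    species is reported as "A" in tables and exports.
    """
    exp.validate()
    if exp.species_a_id <= exp.species_b_id:
        return exp
    # Swap roles: B becomes the left species; its conspecific biomass B_b
    # takes the A_a slot and the cross terms swap soils accordingly.
    return replace(
        exp,
        species_a_id=exp.species_b_id,
        species_b_id=exp.species_a_id,
        A_a=exp.B_b,
        A_b=exp.B_a,
        B_a=exp.A_b,
        B_b=exp.A_a,
        se_A_a=exp.se_B_b,
        se_A_b=exp.se_B_a,
        se_B_a=exp.se_A_b,
        se_B_b=exp.se_A_a,
    )
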