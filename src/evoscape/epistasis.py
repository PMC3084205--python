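"""Pairwise epistasis between adaptive mutations.

Epistasis between mutant alleles x and y is quantified on the selection-
coefficient scale as

    epsilon = s_xy - (s_x + s_y),

where each s is a wild-type-normalised selection coefficient.  The standard
error propagates in quadrature, se_eps = sqrt(se_x^2 + se_y^2 + se_xy^2),
and the interaction is called significant when epsilon falls outside the
95% null interval +/- 1.96 * se_eps around zero (equivalently
|epsilon| > 1.96 * se_eps).  Significant interactions are classified as
magnitude (negative/positive), sign, or reciprocal sign epistasis from the
ordering of the four genotype fitnesses.

The same statistic tests whether the singly adaptive mutations of an
evolved clone additively recapitulate the clone's fitness: a significantly
positive epsilon means the clone is fitter than the sum of its identified
mutations (unexplained adaptive effect), a negative one means sub-additivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .competition_fitness import SelectionEstimate

__all__ = [
    "EpistasisResult",
    "epsilon",
    "classify_epistasis",
    "additivity_test",
    "EPISTASIS_CLASSES",
]

EPISTASIS_CLASSES = ("additive", "negative", "positive", "sign", "reciprocal_sign")

_SIGNIFICANCE_RULE = (
    "significant iff epsilon lies outside the 95% interval +/-1.96*se_eps "
    "centred on the null value 0 (equivalent to |epsilon| > 1.96*se_eps)"
)


@dataclass(frozen=True)
class EpistasisResult:
    epsilon: float
    se_epsilon: float
    ci95: tuple[float, float]
    significant: bool
    class_label: str | None
    inputs: tuple[SelectionEstimate, ...]
    interpretation: str | None = None
    significance_rule: str = _SIGNIFICANCE_RULE

    def __post_init__(self) -> None:
        if self.se_epsilon < 0:
            raise ValueError("se_epsilon must be non-negative")
        if self.class_label is not None and self.class_label not in EPISTASIS_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")

    def as_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "se_epsilon": self.se_epsilon,
            "ci95": list(self.ci95),
            "significant": self.significant,
            "class_label": self.class_label,
            "interpretation": self.interpretation,
            "significance_rule": self.significance_rule,
        }


def _require_normalized(*ests: SelectionEstimate) -> None:
    for e in ests:
        if not e.normalized:
            raise ValueError(
                "all selection estimates must be wild-type normalized "
                "(see normalize_selection)"
            )


def epsilon(
    sx: SelectionEstimate, sy: SelectionEstimate, sxy: SelectionEstimate
) -> EpistasisResult:
    """Epistasis statistic for a mutation pair from the three competitions."""
    _require_normalized(sx, sy, sxy)
    eps = sxy.s - (sx.s + sy.s)
    se = math.sqrt(sx.se**2 + sy.se**2 + sxy.se**2)
    half = 1.96 * se
    return EpistasisResult(
        epsilon=eps,
        se_epsilon=se,
        ci95=(eps - half, eps + half),
        significant=abs(eps) > half,
        class_label=None,
        inputs=(sx, sy, sxy),
    )


def classify_epistasis(
    w0: float,
    wx: float,
    wy: float,
    wxy: float,
    eps: EpistasisResult,
    tol: float = 1e-9,
) -> str:
    """Classify a significant interaction from the four genotype fitnesses.

    The call is "additive" unless ``eps`` is significant (noise never drives
    a sign call).  A mutation "flips" when its fitness effect changes sign
    between the wild-type background and the other mutant's background; one
    flip is sign epistasis, two flips reciprocal sign epistasis (the
    paradigm case: both singles beneficial, the double less fit than either
    single and than wild type).  Otherwise the sign of epsilon gives
    negative or positive magnitude epistasis.

    ``tol`` is the relative tolerance of the consistency check between the
    supplied ``wxy`` and the one implied by ``eps`` under w = 1 + s; raise it
    when the fitnesses and epsilon come from independent noisy estimates.
    """
    if min(w0, wx, wy, wxy) <= 0:
        raise ValueError("fitness values must be positive")
    implied = eps.epsilon - (wxy - wx - wy + w0)
    scale = max(1.0, abs(wxy))
    if abs(implied) > tol * scale:
        raise ValueError(
            f"wxy={wxy} is inconsistent with epsilon={eps.epsilon} "
            f"(deviation {implied:.3g} exceeds tolerance {tol * scale:.3g})"
        )
    if not eps.significant:
        return "additive"
    flip_x = (wx - w0) * (wxy - wy) < 0
    flip_y = (wy - w0) * (wxy - wx) < 0
    if flip_x and flip_y:
        return "reciprocal_sign"
    if flip_x or flip_y:
        return "sign"
    return "negative" if eps.epsilon < 0 else "positive"


def which_locus_flips(w0: float, wx: float, wy: float, wxy: float) -> list[str]:
    """Loci whose fitness effect changes sign across backgrounds ('x'/'y')."""
    flips = []
    if (wx - w0) * (wxy - wy) < 0:
        flips.append("x")
    if (wy - w0) * (wxy - wx) < 0:
        flips.append("y")
    return flips


def additivity_test(
    clone_s: SelectionEstimate, singles: Sequence[SelectionEstimate]
) -> EpistasisResult:
    """Does the sum of singly adaptive mutations recapitulate the clone?

    epsilon = s_clone - sum(s_i); a significantly positive value indicates
    adaptive effects not accounted for by the identified single mutations,
    a negative one sub-additivity between them.
    """
    if len(singles) == 0:
        raise ValueError("need at least one single-mutation estimate")
    _require_normalized(clone_s, *singles)
    eps = clone_s.s - sum(e.s for e in singles)
    se = math.sqrt(clone_s.se**2 + sum(e.se**2 for e in singles))
    half = 1.96 * se
    significant = abs(eps) > half
    if not significant:
        interp = "singles additively recapitulate the clone fitness"
    elif eps > 0:
        interp = "positive: clone fitter than the sum of its identified mutations (unexplained adaptive effect)"
    else:
        interp = "negative: sub-additivity between the identified mutations"
    return EpistasisResult(
        epsilon=eps,
        se_epsilon=se,
        ci95=(eps - half, eps + half),
        significant=significant,
        class_label=None,
        inputs=(clone_s, *singles),
        interpretation=interp,
    )
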