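"""Selection-coefficient estimation from pairwise competition assays.

A mutant and a reference strain compete in continuous culture; both are
counted (e.g. by flow cytometry) at each sampling point.  Under constant
selection the log ratio of the two strains is linear in generations,

    ln(N_mut / N_ref)(g) = ln(N_mut / N_ref)(0) + s * g,

and the per-generation selection coefficient ``s`` is the slope of an
ordinary-least-squares fit of the log ratio against generations.  Estimates
are normalised against a wild-type-vs-wild-type control competition run from
the same cross, and relative fitness is reported as ``w = 1 + s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

__all__ = [
    "CompetitionTimeSeries",
    "SelectionEstimate",
    "select_linear_phase",
    "estimate_selection",
    "pool_replicates",
    "normalize_selection",
    "relative_fitness",
    "ancova_slope_test",
]


@dataclass(frozen=True)
class CompetitionTimeSeries:
    """Counts of two competing strains over generations, one replicate.

    Counts may be non-integral (noise-free expectations); generations must be
    strictly increasing.  ``truncated`` flags a series cut short because one
    strain's count reached zero.
    """

    replicate: str
    generations: np.ndarray
    count_mutant: np.ndarray
    count_reference: np.ndarray
    mutant_label: str = "mutant"
    reference_label: str = "reference"
    truncated: bool = False
    linear_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=float)
        m = np.asarray(self.count_mutant, dtype=float)
        r = np.asarray(self.count_reference, dtype=float)
        if not (g.shape == m.shape == r.shape) or g.ndim != 1:
            raise ValueError("generations and counts must be 1-D and equal length")
        if len(g) >= 2 and not np.all(np.diff(g) > 0):
            raise ValueError("generations must be strictly increasing")
        if np.any(m < 0) or np.any(r < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "count_mutant", m)
        object.__setattr__(self, "count_reference", r)

    def __len__(self) -> int:
        return len(self.generations)

    def log_ratio(self, pseudocount: float = 0.0) -> np.ndarray:
        """Natural log of mutant/reference counts (optionally +pseudocount)."""
        m = self.count_mutant + pseudocount
        r = self.count_reference + pseudocount
        if np.any(m <= 0) or np.any(r <= 0):
            raise ValueError(
                "zero count in series: re-window with select_linear_phase or "
                "set a pseudocount"
            )
        return np.log(m / r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "generations": self.generations,
                "count_mutant": self.count_mutant,
                "count_reference": self.count_reference,
            }
        )


@dataclass(frozen=True)
class SelectionEstimate:
    """A per-generation selection coefficient with its uncertainty.

    ``normalized`` is True only after subtraction of a wild-type control
    (see :func:`normalize_selection`).  ``linear_window`` records the
    generation bounds of the fitted window.
    """

    s: float
    se: float
    ci95: tuple[float, float]
    n_replicates: int = 1
    normalized: bool = False
    linear_window: tuple[float, float] | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.s <= hi + 1e-12):
            raise ValueError("ci95 must contain the point estimate")

    def as_dict(self) -> dict:
        return {
            "s": self.s,
            "se": self.se,
            "ci95": list(self.ci95),
            "n_replicates": self.n_replicates,
            "normalized": self.normalized,
            "linear_window": list(self.linear_window) if self.linear_window else None,
            "n_points": self.n_points,
        }


def _ols_slope(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope SE and R^2 of y ~ g by ordinary least squares."""
    res = scipy.stats.linregress(g, y)
    return float(res.slope), float(res.stderr), float(res.rvalue**2)


def select_linear_phase(
    series: CompetitionTimeSeries,
    min_points: int = 4,
    max_dropped_fraction: float = 0.5,
) -> CompetitionTimeSeries:
    """Pick the contiguous sub-series best described by a straight line.

    Among all contiguous windows with at least ``min_points`` samples, all
    counts positive, and at most ``max_dropped_fraction`` of the samples
    dropped, returns the window maximising the R^2 of the log-ratio vs
    generations regression.  Ties favour the longer, then earlier, window;
    a perfectly linear series is returned unchanged.
    """
    n = len(series)
    if min_points < 3:
        raise ValueError("min_points must be >= 3 for a meaningful regression")
    if min_points > n:
        raise ValueError(
            f"min_points={min_points} exceeds series length {n}: no admissible window"
        )
    max_drop = int(np.floor(max_dropped_fraction * n))
    g = series.generations
    m = series.count_mutant
    r = series.count_reference
    ok = (m > 0) & (r > 0)

    best: tuple[float, int, int] | None = None  # (r2, length, -start)
    best_bounds: tuple[int, int] | None = None
    for i in range(n):
        for j in range(i + min_points, n + 1):
            if (n - (j - i)) > max_drop:
                continue
            if not ok[i:j].all():
                continue
            y = np.log(m[i:j] / r[i:j])
            if np.allclose(y, y[0]):  # flat line: R^2 undefined, treat as perfect
                r2 = 1.0
            else:
                _, _, r2 = _ols_slope(g[i:j], y)
            key = (round(r2, 12), j - i, -i)
            if best is None or key > best:
                best, best_bounds = key, (i, j)
    if best_bounds is None:
        raise ValueError(
            "no admissible window: every candidate violates the positive-count, "
            f"min_points={min_points} or max_dropped_fraction={max_dropped_fraction} "
            "constraint"
        )
    i, j = best_bounds
    return replace(
        series,
        generations=g[i:j],
        count_mutant=m[i:j],
        count_reference=r[i:j],
        linear_window=(float(g[i]), float(g[j - 1])),
    )


def estimate_selection(
    series: CompetitionTimeSeries, pseudocount: float = 0.0
) -> SelectionEstimate:
    """OLS estimate of the selection coefficient from one competition series.

    The 95% CI uses the t distribution with n-2 degrees of freedom on the
    regression slope.  Zero counts inside the window are an error unless a
    pseudocount is supplied.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples for a regression")
    y = series.log_ratio(pseudocount)
    g = series.generations
    slope, se, _ = _ols_slope(g, y)
    n = len(g)
    tcrit = float(scipy.stats.t.ppf(0.975, n - 2))
    if not np.isfinite(se):  # exactly collinear data (zero residuals)
        se = 0.0
    ci = (slope - tcrit * se, slope + tcrit * se)
    window = series.linear_window or (float(g[0]), float(g[-1]))
    return SelectionEstimate(
        s=slope, se=se, ci95=ci, n_replicates=1, normalized=False,
        linear_window=window, n_points=n,
    )


def pool_replicates(estimates: Sequence[SelectionEstimate]) -> SelectionEstimate:
    """Pool replicate estimates: mean s, SEM across replicates, z-based CI.

    A single estimate passes through unchanged (its regression SE is kept).
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    flags = {e.normalized for e in estimates}
    if len(flags) > 1:
        raise ValueError("cannot pool normalized with unnormalized estimates")
    if len(estimates) == 1:
        return estimates[0]
    svals = np.array([e.s for e in estimates])
    s = float(svals.mean())
    se = float(svals.std(ddof=1) / np.sqrt(len(svals)))
    windows = [e.linear_window for e in estimates if e.linear_window]
    window = (
        (min(w[0] for w in windows), max(w[1] for w in windows)) if windows else None
    )
    return SelectionEstimate(
        s=s, se=se, ci95=(s - 1.96 * se, s + 1.96 * se),
        n_replicates=len(estimates), normalized=flags.pop(), linear_window=window,
    )


def normalize_selection(
    mutant: SelectionEstimate, wt_control: SelectionEstimate
) -> SelectionEstimate:
    """Subtract the wild-type control selection coefficient from the mutant's.

    SEs combine in quadrature.  Normalising twice is refused.
    """
    if mutant.normalized or wt_control.normalized:
        raise ValueError("inputs must be unnormalized (double normalization refused)")
    s = mutant.s - wt_control.s
    se = float(np.hypot(mutant.se, wt_control.se))
    return SelectionEstimate(
        s=s, se=se, ci95=(s - 1.96 * se, s + 1.96 * se),
        n_replicates=mutant.n_replicates, normalized=True,
        linear_window=mutant.linear_window, n_points=mutant.n_points,
    )


@dataclass(frozen=True)
class RelativeFitness:
    """Relative fitness w of a mutant, wild-type competitor scaled to w = 1."""

    w: float
    ci95: tuple[float, float]
    convention: str = "w = 1 + s"


def relative_fitness(est: SelectionEstimate) -> RelativeFitness:
    """Map a normalised selection coefficient to relative fitness w = 1 + s."""
    if not est.normalized:
        raise ValueError("relative fitness requires a normalized estimate")
    lo, hi = est.ci95
    return RelativeFitness(w=1.0 + est.s, ci95=(1.0 + lo, 1.0 + hi))


def ancova_slope_test(
    mutant_series: CompetitionTimeSeries, wt_series: CompetitionTimeSeries
) -> tuple[float, float]:
    """Nested-model F test for equal slopes of mutant and control series.

    Compares ``ln_ratio ~ generations + group`` (common slope) against
    ``ln_ratio ~ generations * group`` (independent slopes); the F statistic
    has (1, n - 4) degrees of freedom.  Returns ``(F, p)``.
    """
    frames = []
    for grp, ser in (("mutant", mutant_series), ("wt", wt_series)):
        if len(ser) < 3:
            raise ValueError("both series need at least 3 points")
        frames.append(
            pd.DataFrame(
                {"g": ser.generations, "y": ser.log_ratio(), "group": grp}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    if len(data) < 5:
        raise ValueError("too few points for the independent-slope model")
    reduced = sm.OLS.from_formula("y ~ g + C(group)", data).fit()
    full = sm.OLS.from_formula("y ~ g * C(group)", data).fit()
    table = anova_lm(reduced, full)
    f = float(table["F"].iloc[1])
    p = float(table["Pr(>F)"].iloc[1])
    if not np.isfinite(f):  # identical slopes, zero residual: no evidence of difference
        f, p = 0.0, 1.0
    return f, p
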