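"""Copy-number estimation for a tandem gene amplification.

Two independent routes estimate the copy number of an amplified segment
(the HXT6/7 glucose-transporter array in the study system this package
models):

* **sequencing depth** — the evolved clone's per-base depth is scaled to the
  ancestor's average depth and divided by the ancestor's per-base depth;
  a centred running median smooths the ratio, and the median of the
  smoothed ratio inside the amplified segment is the copy-number estimate;

* **qPCR (delta-delta-Ct)** — target-locus Ct values are normalised to a
  non-varying reference locus and to a calibrator sample of known copy
  number; copy number = calibrator_copies * E^(-ddCt) with amplification
  efficiency E (default 2), summarised over replicates as mean with a
  95% CI of mean +/- 1.96 * SEM.

A minimum count of unequal mitotic recombination events needed to build a
tandem array follows from a doubling model: each event can at most double
the number of promoter units, so an array with p promoters needs at least
ceil(log2(p)) events.  The array model predicts one more ORF than promoter
copies, which is validated when both counts are supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "QpcrMeasurement",
    "CopyNumberEstimate",
    "QpcrResult",
    "coverage_ratio",
    "running_median",
    "segment_copy_number",
    "qpcr_copy_number",
    "min_recombination_events",
]


@dataclass(frozen=True)
class DepthProfile:
    """Per-base read depth over a contiguous 1-based position range."""

    chrom: str
    start: int  # 1-based position of depth[0]
    depth: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depth, dtype=float)
        if d.ndim != 1:
            raise ValueError("depth must be 1-D")
        if np.any(d < 0):
            raise ValueError("depth must be non-negative")
        if self.start < 1:
            raise ValueError("positions are 1-based; start must be >= 1")
        object.__setattr__(self, "depth", d)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.depth))

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for a target and reference locus, plus calibrator.

    ``ct_target``/``ct_reference`` are per-replicate cycle thresholds for the
    sample; ``calibrator_ct_target``/``calibrator_ct_reference`` the same for
    the calibrator sample whose target copy number is known
    (``calibrator_copies``).
    """

    target_locus: str
    reference_locus: str
    ct_target: tuple
    ct_reference: tuple
    calibrator_ct_target: tuple
    calibrator_ct_reference: tuple
    calibrator_copies: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference", "calibrator_ct_target", "calibrator_ct_reference"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size < 1 or not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} must hold at least one finite Ct value")
        if len(self.ct_target) != len(self.ct_reference):
            raise ValueError("target and reference replicate counts differ")


@dataclass(frozen=True)
class CopyNumberEstimate:
    estimate: float
    baseline: float  # median smoothed ratio outside the region, for contrast
    region: tuple[int, int]
    n_bases: int


@dataclass(frozen=True)
class QpcrResult:
    copy_number: float
    sem: float | None
    ci95: tuple[float, float] | None
    n_replicates: int
    per_replicate: tuple


def coverage_ratio(clone: DepthProfile, ancestor: DepthProfile) -> np.ndarray:
    """Per-base clone/ancestor depth ratio after mean normalisation.

    ratio_i = (clone_i * mean(ancestor) / mean(clone)) / ancestor_i, which is
    invariant to global scaling of either profile.  Positions where the
    ancestor has zero depth yield NaN, never infinities.
    """
    if clone.chrom != ancestor.chrom or clone.start != ancestor.start or len(clone) != len(ancestor):
        raise ValueError("clone and ancestor profiles must cover identical ranges")
    if clone.depth.mean() == 0:
        raise ValueError("clone profile has zero mean depth")
    scaled = clone.depth * (ancestor.depth.mean() / clone.depth.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ancestor.depth > 0, scaled / ancestor.depth, np.nan)
    return ratio


def running_median(values, window: int) -> np.ndarray:
    """Centred running median; windows shrink symmetrically at the edges.

    Output has the input's length.  NaNs are ignored within each window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def segment_copy_number(
    smoothed_ratio: np.ndarray,
    region: tuple[int, int],
    profile_start: int = 1,
) -> CopyNumberEstimate:
    """Median smoothed ratio inside a 1-based closed region = copy number.

    The median of the smoothed ratio outside the region is reported as the
    flanking baseline for contrast.
    """
    lo, hi = region
    if lo > hi:
        raise ValueError("empty region")
    i = lo - profile_start
    j = hi - profile_start + 1
    if i < 0 or j > len(smoothed_ratio):
        raise ValueError("region outside the profile")
    inside = np.asarray(smoothed_ratio[i:j], dtype=float)
    outside = np.concatenate([smoothed_ratio[:i], smoothed_ratio[j:]])
    if np.all(np.isnan(inside)):
        raise ValueError("region has no usable ratio values")
    baseline = float(np.nanmedian(outside)) if outside.size else float("nan")
    return CopyNumberEstimate(
        estimate=float(np.nanmedian(inside)),
        baseline=baseline,
        region=(lo, hi),
        n_bases=j - i,
    )


def qpcr_copy_number(m: QpcrMeasurement, efficiency: float = 2.0) -> QpcrResult:
    """Delta-delta-Ct copy number with a 95% CI over replicates.

    Per replicate dCt = Ct_target - Ct_reference; ddCt subtracts the
    calibrator's mean dCt; copy number = calibrator_copies * E^(-ddCt).
    A single replicate yields a point estimate with undefined CI (flagged
    by ``sem is None``).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    dct = np.asarray(m.ct_target, dtype=float) - np.asarray(m.ct_reference, dtype=float)
    dct_cal = float(
        np.mean(np.asarray(m.calibrator_ct_target, dtype=float)
                - np.asarray(m.calibrator_ct_reference, dtype=float))
    )
    ddct = dct - dct_cal
    copies = m.calibrator_copies * efficiency ** (-ddct)
    n = len(copies)
    point = float(copies.mean())
    if n == 1:
        return QpcrResult(point, None, None, 1, tuple(copies))
    sem = float(copies.std(ddof=1) / math.sqrt(n))
    return QpcrResult(
        copy_number=point,
        sem=sem,
        ci95=(point - 1.96 * sem, point + 1.96 * sem),
        n_replicates=n,
        per_replicate=tuple(copies),
    )


def min_recombination_events(promoter_copies: int, orf_copies: int | None = None) -> int:
    """Minimum unequal-recombination events to reach a promoter count.

    One event can at most double the promoter count, starting from the
    single ancestral promoter, so the minimum is ceil(log2(promoter_copies)).
    When ``orf_copies`` is supplied it is validated against the array model
    ORFs = promoters + 1 (a deviation warns but does not change the count).
    """
    if promoter_copies < 1:
        raise ValueError("promoter_copies must be >= 1")
    if orf_copies is not None and orf_copies != promoter_copies + 1:
        warnings.warn(
            f"array model violated: expected {promoter_copies + 1} ORFs for "
            f"{promoter_copies} promoters, got {orf_copies} "
            f"(deviation {orf_copies - promoter_copies - 1:+d})",
            stacklevel=2,
        )
    events = 0
    reachable = 1
    while reachable < promoter_copies:
        reachable *= 2
        events += 1
    return events
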