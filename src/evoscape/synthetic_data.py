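"""Synthetic inputs with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here, emulating the
study design: pairwise competition chemostats sampled every 6 h at a
dilution rate of 0.2 h^-1 over ~20-25 generations with flow-cytometry
counting noise; ancestor/evolved per-site allele-count tables with
constructed true SNPs/indels plus background noise; per-base depth
profiles with an amplified tandem segment; two-locus genotype-fitness
scenarios for each epistasis class; and clone genotype tables with
configurable co-occurrence.

Noise models are the simplest ones consistent with the instruments:
binomial counting for two-colour proportions, Poisson counting for
shotgun depth.  With ``noise=False`` every generator returns its
closed-form expectation exactly.  All randomness flows from one seed
through named substreams, so adding a generator never perturbs the
output of another, and a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .competition_fitness import CompetitionTimeSeries
from .variant_filters import IndelThresholds, VariantRecord
from .copy_number import DepthProfile

__all__ = [
    "SimulationConfig",
    "LandscapeScenario",
    "SCENARIO_DEFAULTS",
    "gen_competition_series",
    "gen_landscape_scenario",
    "gen_variant_tables",
    "gen_coverage_profiles",
    "gen_clone_genotypes",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the competition-chemostat simulator.

    Defaults mirror the modelled experiment: triplicate competitions in a
    chemostat diluted at 0.2 h^-1, sampled every 6 h for ~24 generations;
    30,000 cytometry events per sample (a typical acquisition; the assay
    itself fixes no value).  Generations accrue as dilution_rate * t / ln 2.
    """

    seed: int = 0
    n_replicates: int = 3
    events_per_sample: int = 30_000
    sampling_interval_h: float = 6.0
    dilution_rate_per_h: float = 0.2
    total_generations: float = 24.0

    def __post_init__(self) -> None:
        if self.events_per_sample <= 0:
            raise ValueError("events_per_sample must be positive")
        if self.total_generations <= 0:
            raise ValueError("total_generations must be positive")
        if self.sampling_interval_h <= 0 or self.dilution_rate_per_h <= 0:
            raise ValueError("sampling interval and dilution rate must be positive")

    @property
    def generations_per_sample(self) -> float:
        return self.dilution_rate_per_h * self.sampling_interval_h / LN2

    def sample_generations(self) -> np.ndarray:
        """Generation stamps of the sampling grid, 0 .. total_generations."""
        n = int(math.floor(self.total_generations / self.generations_per_sample)) + 1
        return np.arange(n) * self.generations_per_sample


def gen_competition_series(
    s_true: float,
    cfg: SimulationConfig = SimulationConfig(),
    initial_log_ratio: float = 0.0,
    noise: bool = True,
) -> list[CompetitionTimeSeries]:
    """Simulate pairwise-competition count series, one per replicate.

    The expected log mutant/reference ratio is linear in generations with
    slope ``s_true``; at each sampling point ``events_per_sample`` cells are
    classified binomially by the current mutant proportion.  With
    ``noise=False`` expected (fractional) counts are returned, so the log
    ratio is exactly linear.  A replicate in which a count hits 0 or the
    full event count is truncated there and flagged, never divided by zero.
    """
    g = cfg.sample_generations()
    log_ratio = initial_log_ratio + s_true * g
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-log_ratio))  # mutant proportion
    if p[0] <= 0.0 or p[0] >= 1.0:
        raise ValueError("initial mutant proportion must lie strictly inside (0, 1)")
    saturated = np.nonzero((p <= 0.0) | (p >= 1.0))[0]
    sat_truncated = saturated.size > 0
    if sat_truncated:  # proportion hit 0/1 exactly (floating point): cut, never divide by zero
        cut = saturated[0]
        g, p = g[:cut], p[:cut]
    out = []
    for rep in range(cfg.n_replicates):
        if noise:
            rng = substream(cfg.seed, f"competition/{rep}")
            m = rng.binomial(cfg.events_per_sample, p).astype(float)
            r = cfg.events_per_sample - m
            boundary = np.nonzero((m == 0) | (r == 0))[0]
            truncated = boundary.size > 0
            if truncated:
                cut = boundary[0]
                g_rep, m, r = g[:cut], m[:cut], r[:cut]
            else:
                g_rep = g
        else:
            m = cfg.events_per_sample * p
            r = cfg.events_per_sample * (1.0 - p)
            g_rep, truncated = g, False
        truncated = truncated or sat_truncated
        out.append(
            CompetitionTimeSeries(
                replicate=f"rep{rep + 1}",
                generations=g_rep,
                count_mutant=m,
                count_reference=r,
                truncated=truncated,
            )
        )
    return out


# Default two-locus fitness patterns, one per epistasis class.  Values sit in
# the study's range of single-mutant relative fitnesses (~1.1-1.45); the
# reciprocal-sign default mirrors the mth1 x HXT6/7-amplification pattern
# (both singles beneficial, double mutant less fit than wild type).
SCENARIO_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "additive": (1.0, 1.10, 1.10, 1.20),
    "negative": (1.0, 1.20, 1.30, 1.35),
    "positive": (1.0, 1.10, 1.15, 1.35),
    "sign": (1.0, 1.10, 1.25, 1.18),
    "reciprocal_sign": (1.0, 1.25, 1.35, 0.85),
}


@dataclass(frozen=True)
class LandscapeScenario:
    """A named two-locus fitness pattern (w0, wx, wy, wxy).

    The name must be consistent with the ordering the fitnesses imply;
    construction validates the defining inequalities of each class.
    """

    name: str
    w0: float = 1.0
    wx: float | None = None
    wy: float | None = None
    wxy: float | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_DEFAULTS:
            raise ValueError(
                f"unknown scenario {self.name!r}; choose from {sorted(SCENARIO_DEFAULTS)}"
            )
        defaults = SCENARIO_DEFAULTS[self.name]
        for fname, default in zip(("w0", "wx", "wy", "wxy"), defaults):
            if getattr(self, fname) is None:
                object.__setattr__(self, fname, default)
        if self.w0 <= 0 or min(self.wx, self.wy, self.wxy) <= 0:
            raise ValueError("fitness values must be positive")
        self._validate()

    def _validate(self) -> None:
        w0, wx, wy, wxy = self.w0, self.wx, self.wy, self.wxy
        additive = w0 + (wx - w0) + (wy - w0)
        if self.name == "additive":
            if not math.isclose(wxy, additive, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"additive scenario requires wxy = wx + wy - w0 ({additive}), got {wxy}"
                )
        elif self.name == "negative":
            if not wxy < additive:
                raise ValueError(f"negative scenario requires wxy < wx + wy - w0 = {additive}")
            if not wxy > max(wx, wy):
                raise ValueError(f"negative scenario requires wxy > max(wx, wy) = {max(wx, wy)}")
        elif self.name == "positive":
            if not wxy > additive:
                raise ValueError(f"positive scenario requires wxy > wx + wy - w0 = {additive}")
        elif self.name == "sign":
            flips = ((wx - w0) * (wxy - wy) < 0) + ((wy - w0) * (wxy - wx) < 0)
            if flips != 1:
                raise ValueError(
                    "sign scenario requires exactly one mutation to flip effect sign "
                    f"across backgrounds; these fitnesses give {flips} flips"
                )
        elif self.name == "reciprocal_sign":
            if not (wx > w0 and wy > w0):
                raise ValueError("reciprocal_sign scenario requires wx > w0 and wy > w0")
            if not (wxy < w0 and wxy < min(wx, wy)):
                raise ValueError(
                    f"reciprocal_sign scenario requires wxy < w0 and wxy < min(wx, wy) = {min(wx, wy)}"
                )


def gen_landscape_scenario(scenario: LandscapeScenario) -> pd.DataFrame:
    """Genotype-fitness table {00, 10, 01, 11} for a validated scenario."""
    return pd.DataFrame(
        {
            "genotype": ["00", "10", "01", "11"],
            "fitness": [scenario.w0, scenario.wx, scenario.wy, scenario.wxy],
            "scenario": scenario.name,
        }
    )


def _distribute_errors(rng, n_errors: int, bases: list[str]) -> dict:
    """Split n_errors uniformly over the given bases."""
    counts = dict.fromkeys(bases, 0)
    if n_errors > 0 and bases:
        for b in rng.choice(bases, size=n_errors):
            counts[b] += 1
    return counts


def gen_variant_tables(
    n_sites: int,
    true_snps: int = 0,
    true_indels: int = 0,
    mean_coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Paired ancestor/evolved allele-count tables with ground truth.

    True SNPs and indels are constructed so that they pass every filter
    rule; background sites are constructed to fail at least one rule each
    (most share the reference consensus; some are deliberate near-misses:
    high-N sites, intermediate-frequency sites, multi-allelic sites and
    under-covered indels).  Sequencing noise at rate ``error_rate`` is
    injected but capped below the rule margins at constructed-true sites,
    so the emitted ``expected_pass`` labels partition the sites exactly
    under the default thresholds.

    Returns ``(ancestor_records, evolved_records, truth)`` where ``truth``
    has one row per site with its kind and expected filter outcome.
    """
    if true_snps + true_indels > n_sites:
        raise ValueError("more true variants than sites")
    if mean_coverage <= 0 and n_sites > 0:
        raise ValueError("coverage must be positive")
    rng = substream(seed, "variants")
    indel_t = IndelThresholds()
    chrom = "chr_sim"
    bases = list("ACGT")

    if n_sites == 0:
        return [], [], pd.DataFrame(columns=["pos", "kind", "expected_pass", "mode"])
    positions = rng.choice(np.arange(1, n_sites + 1), size=n_sites, replace=False)
    snp_pos = sorted(positions[:true_snps].tolist())
    indel_pos = sorted(positions[true_snps : true_snps + true_indels].tolist())
    if len(set(snp_pos) | set(indel_pos)) != true_snps + true_indels:
        raise ValueError("duplicated variant positions")
    background_pos = sorted(positions[true_snps + true_indels :].tolist())

    anc_records: list[VariantRecord] = []
    evo_records: list[VariantRecord] = []
    truth_rows: list[dict] = []

    def coverage() -> int:
        return max(15, int(rng.poisson(mean_coverage)))

    def errors(cov: int, cap: int) -> int:
        """Noise draw capped so constructed rule margins survive."""
        n = int(rng.binomial(cov, error_rate)) if error_rate > 0 else 0
        return min(n, max(cap, 0))

    def make_record(pos, ref, counts, indels, sample, cov):
        return VariantRecord(
            chrom=chrom, pos=int(pos), ref_base=ref, coverage=cov,
            base_counts=counts, indel_counts=indels, sample=sample,
        )

    for pos in snp_pos:
        ref = str(rng.choice(bases))
        alt = str(rng.choice([b for b in bases if b != ref]))
        cov_a, cov_e = coverage(), coverage()
        # ancestor: essentially pure reference; errors kept below the 0.1 split rule
        e_a = errors(cov_a, int(0.1 * cov_a) - 1)
        anc_counts = {ref: cov_a - e_a, **_distribute_errors(rng, e_a, [b for b in bases if b != ref])}
        # evolved: alt majority; ref/other noise kept below the majority and split rules
        e_e = errors(cov_e, min(int(0.2 * cov_e), cov_e - int(0.6 * cov_e) - 1))
        other = [b for b in bases if b not in (ref, alt)]
        e_other = min(e_e // 2, max(int(0.15 * (cov_e - e_e)), 0))
        evo_counts = {alt: cov_e - e_e, ref: e_e - e_other,
                      **_distribute_errors(rng, e_other, other)}
        anc_records.append(make_record(pos, ref, anc_counts, {}, "ancestor", cov_a))
        evo_records.append(make_record(pos, ref, evo_counts, {}, "evolved", cov_e))
        truth_rows.append({"pos": pos, "kind": "snp", "expected_pass": True, "mode": "true_snp"})

    for pos in indel_pos:
        ref = str(rng.choice(bases))
        allele = "+" + str(rng.choice(bases))
        cov_a = coverage()
        cov_e = max(coverage(), indel_t.min_coverage + 5)
        n_indel = int(0.75 * cov_e)  # >50% of coverage, single allele so top-two = 1
        evo_counts = {ref: cov_e - n_indel}  # ref matches 25% < 50%
        anc_e = errors(cov_a, int((n_indel / cov_e - indel_t.min_shared_allele_delta) * cov_a) - 1)
        anc_counts = {ref: cov_a - anc_e}
        anc_indels = {allele: anc_e} if anc_e > 0 else {}
        anc_records.append(make_record(pos, ref, anc_counts, anc_indels, "ancestor", cov_a))
        evo_records.append(make_record(pos, ref, evo_counts, {allele: n_indel}, "evolved", cov_e))
        truth_rows.append({"pos": pos, "kind": "indel", "expected_pass": True, "mode": "true_indel"})

    # background failure modes, cycled deterministically
    modes = ["shared_consensus", "high_n", "intermediate_freq", "multiallelic", "low_cov_indel"]
    for i, pos in enumerate(background_pos):
        ref = str(rng.choice(bases))
        alt = str(rng.choice([b for b in bases if b != ref]))
        mode = "shared_consensus" if i % 4 != 0 else modes[(i // 4) % len(modes)]
        cov_a, cov_e = coverage(), coverage()
        e_a = errors(cov_a, int(0.1 * cov_a) - 1)
        anc_counts = {ref: cov_a - e_a, **_distribute_errors(rng, e_a, [b for b in bases if b != ref])}
        anc_indel: dict = {}
        evo_indel: dict = {}
        if mode == "shared_consensus":
            e_e = errors(cov_e, int(0.1 * cov_e) - 1)
            evo_counts = {ref: cov_e - e_e, **_distribute_errors(rng, e_e, [b for b in bases if b != ref])}
        elif mode == "high_n":
            n_n = max(int(0.2 * cov_e), 1)
            evo_counts = {alt: cov_e - n_n, "N": n_n}
        elif mode == "intermediate_freq":
            n_alt = int(0.3 * cov_e)
            evo_counts = {ref: cov_e - n_alt, alt: n_alt}
        elif mode == "multiallelic":
            other = [b for b in bases if b not in (ref, alt)][0]
            n_var = int(0.35 * cov_e)
            evo_counts = {ref: cov_e - 2 * n_var, alt: n_var, other: n_var}
        else:  # low_cov_indel
            cov_e = indel_t.min_coverage  # fails the strict > rule
            n_indel = int(0.75 * cov_e)
            evo_counts = {ref: cov_e - n_indel}
            evo_indel = {"+T": n_indel}
        anc_records.append(make_record(pos, ref, anc_counts, anc_indel, "ancestor", cov_a))
        evo_records.append(make_record(pos, ref, evo_counts, evo_indel, "evolved", cov_e))
        truth_rows.append({"pos": pos, "kind": "background", "expected_pass": False, "mode": mode})

    key = lambda r: (r.chrom, r.pos)
    anc_records.sort(key=key)
    evo_records.sort(key=key)
    truth = pd.DataFrame(truth_rows, columns=["pos", "kind", "expected_pass", "mode"])
    truth = truth.sort_values("pos").reset_index(drop=True)
    return anc_records, evo_records, truth


def gen_coverage_profiles(
    length: int,
    mean_depth: float = 30.0,
    amp_start: int = 1,
    amp_end: int = 1,
    amp_copies: int = 1,
    seed: int = 0,
    noise: bool = True,
    chrom: str = "chr_sim",
) -> tuple[DepthProfile, DepthProfile]:
    """Ancestor and clone depth profiles with an amplified segment.

    The clone's expected depth is ``mean_depth * amp_copies`` inside the
    1-based closed segment [amp_start, amp_end] and ``mean_depth`` outside;
    per-base counts are Poisson unless ``noise=False``.  Returns
    ``(ancestor, clone)``.
    """
    if amp_copies < 1:
        raise ValueError("amp_copies must be >= 1")
    if not (1 <= amp_start <= amp_end <= length):
        raise ValueError("amplified segment must satisfy 1 <= start <= end <= length")
    expect_anc = np.full(length, float(mean_depth))
    expect_clone = expect_anc.copy()
    expect_clone[amp_start - 1 : amp_end] *= amp_copies
    if noise:
        rng = substream(seed, "coverage")
        anc = rng.poisson(expect_anc).astype(float)
        clone = rng.poisson(expect_clone).astype(float)
    else:
        anc, clone = expect_anc, expect_clone
    return (
        DepthProfile(chrom=chrom, start=1, depth=anc),
        DepthProfile(chrom=chrom, start=1, depth=clone),
    )


def gen_clone_genotypes(
    n_clones: int,
    freq_a: float,
    freq_b: float,
    allow_double: bool = True,
    seed: int = 0,
    locus_a: str = "mth1",
    locus_b: str = "hxt_amp",
) -> pd.DataFrame:
    """Clone genotype table with configurable co-occurrence.

    With ``allow_double=True`` the two loci are sampled independently at
    their marginal frequencies; with ``allow_double=False`` each clone is
    one of {A only, B only, neither} with probabilities (freq_a, freq_b,
    1 - freq_a - freq_b), so no clone carries both mutant alleles while
    the marginals are preserved (requires freq_a + freq_b <= 1).
    """
    for f in (freq_a, freq_b):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    rng = substream(seed, "genotypes")
    if allow_double:
        a = rng.random(n_clones) < freq_a
        b = rng.random(n_clones) < freq_b
    else:
        if freq_a + freq_b > 1.0:
            raise ValueError(
                "allow_double=False is infeasible when freq_a + freq_b > 1"
            )
        cat = rng.choice(3, size=n_clones, p=[freq_a, freq_b, 1.0 - freq_a - freq_b])
        a = cat == 0
        b = cat == 1
    return pd.DataFrame(
        {
            "clone": [f"clone{i + 1}" for i in range(n_clones)],
            locus_a: a.astype(int),
            locus_b: b.astype(int),
        }
    )
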