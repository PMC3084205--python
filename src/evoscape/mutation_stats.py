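"""Neutral-mutation statistics and mutation-capacity scans.

Under neutrality, mutations accumulate in an asexual lineage as a Poisson
process: over g generations a genome of G base pairs with per-base mutation
rate mu carries on average lambda = G * mu * g mutations, and the chance of
k or more is the upper Poisson tail.  The whole population supplies
N * G * mu new mutations per generation.  A codon scan counts how many sense
codons of a coding sequence are a single nucleotide substitution away from a
stop codon (the gene's capacity for nonsense mutations), and a genotype
cross-tabulation counts how often two mutations co-occur among clones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import scipy.stats

__all__ = [
    "NeutralModel",
    "expected_neutral_mutations",
    "poisson_tail",
    "mutation_supply",
    "nonsense_capacity",
    "cooccurrence_count",
    "CooccurrenceCounts",
    "exclusivity_probability",
    "STOP_CODONS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"


@dataclass(frozen=True)
class NeutralModel:
    """Parameters of the neutral-accumulation model.

    genome_size in bp, mu in mutations per bp per generation, generations
    elapsed, and (for the supply calculation) the population size in cells.
    Defaults are the S. cerevisiae genome size, the measured per-base rate
    and the chemostat census size used throughout this package.
    """

    genome_size: float = 1.2e7
    mu: float = 5.12e-10
    generations: float = 0.0
    pop_size: float = 2e9

    def __post_init__(self) -> None:
        if min(self.genome_size, self.mu, self.generations, self.pop_size) < 0:
            raise ValueError("all model parameters must be non-negative")


def expected_neutral_mutations(m: NeutralModel) -> float:
    """Expected neutral mutation count lambda = G * mu * generations."""
    return m.genome_size * m.mu * m.generations


def poisson_tail(lam: float, k: int) -> float:
    """P(X >= k) for X ~ Poisson(lam), computed stably via the survival function."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if k != int(k) or k < 0:
        raise ValueError("k must be a non-negative integer")
    k = int(k)
    if k == 0:
        return 1.0
    return float(scipy.stats.poisson.sf(k - 1, lam))


def mutation_supply(m: NeutralModel) -> float:
    """New mutations arising per generation in the whole population, N*G*mu."""
    return m.pop_size * m.genome_size * m.mu


def nonsense_capacity(cds: str) -> tuple[int, int]:
    """Count sense codons one substitution away from a stop codon.

    ``cds`` is a coding sequence (A/C/G/T, length divisible by 3).  Returns
    ``(reachable, total_sense_codons)``: how many sense codons have at least
    one of their nine single-nucleotide variants equal to TAA, TAG or TGA,
    out of all sense codons.  The terminal stop codon is excluded from both
    counts; an internal stop codon raises a warning and is excluded too.
    A codon counts once no matter how many stop-reaching substitutions it has.
    """
    seq = str(cds).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    if set(seq) - set(_BASES):
        bad = sorted(set(seq) - set(_BASES))
        raise ValueError(f"ambiguous or invalid bases in sequence: {bad}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    reachable = 0
    total = 0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            warnings.warn(
                f"internal stop codon {codon} at codon {i + 1}; excluded from the scan",
                stacklevel=2,
            )
            continue
        total += 1
        if any(
            codon[:p] + b + codon[p + 1 :] in STOP_CODONS
            for p in range(3)
            for b in _BASES
            if b != codon[p]
        ):
            reachable += 1
    return reachable, total


@dataclass(frozen=True)
class CooccurrenceCounts:
    n_clones: int
    n_a_only: int
    n_b_only: int
    n_both: int
    n_neither: int
    n_unknown: int = 0

    def __post_init__(self) -> None:
        parts = self.n_a_only + self.n_b_only + self.n_both + self.n_neither + self.n_unknown
        if parts != self.n_clones:
            raise ValueError("counts do not partition the clone table")


def cooccurrence_count(table, locus_a: str, locus_b: str) -> CooccurrenceCounts:
    """Cross-tabulate mutant-allele carriage at two loci over a clone table.

    ``table`` is a DataFrame with one row per clone and 0/1 genotype columns
    named ``locus_a`` and ``locus_b``.  Clones with a missing call at either
    locus are counted in the ``unknown`` bin, never dropped.
    """
    for locus in (locus_a, locus_b):
        if locus not in table.columns:
            raise ValueError(f"locus {locus!r} not present in the genotype table")
    a = table[locus_a]
    b = table[locus_b]
    known = a.notna() & b.notna()
    a_bool = a[known].astype(int).astype(bool)
    b_bool = b[known].astype(int).astype(bool)
    return CooccurrenceCounts(
        n_clones=len(table),
        n_a_only=int((a_bool & ~b_bool).sum()),
        n_b_only=int((~a_bool & b_bool).sum()),
        n_both=int((a_bool & b_bool).sum()),
        n_neither=int((~a_bool & ~b_bool).sum()),
        n_unknown=int((~known).sum()),
    )


def exclusivity_probability(counts: CooccurrenceCounts) -> float:
    """P(zero double mutants | marginal counts) under random assortment.

    Hypergeometric probability that, with the observed numbers of carriers
    of each mutation among the known clones, no clone carries both.  This is
    auxiliary descriptive plumbing, not a statistic the mutual-exclusivity
    observation depends on.
    """
    n = counts.n_clones - counts.n_unknown
    n_a = counts.n_a_only + counts.n_both
    n_b = counts.n_b_only + counts.n_both
    return float(scipy.stats.hypergeom.pmf(0, n, n_a, n_b))
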