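"""Heuristic post-caller filters for ancestor/evolved variant candidates.

Candidate SNPs and indels from an evolved clone are compared site-by-site
with the sequenced ancestor; a variant survives only if the two samples
disagree in consensus and a set of allele-balance rules hold.  The rules
operate on per-site allele counts (a pileup summary), not on reads: read
alignment and primary variant calling are upstream and out of scope here.

SNP rules (all must hold, evaluated on the paired records):
  * proportion of N bases at the position < 0.1 (denominator: all reads);
  * the majority non-reference base accounts for > 80% of all
    non-reference bases (denominator: non-N, non-reference reads) in the
    strain carrying the candidate allele;
  * the non-reference proportion (denominator: non-N reads) is < 0.1 in
    one strain and > 0.5 in the other;
  * ancestor and evolved consensus bases differ.

Indel rules (all must hold):
  * evolved coverage > 10 (strictly);
  * indel calls > 50% of evolved coverage;
  * the two most frequent indel alleles together > 80% of indel calls;
  * reference matches < 50% of evolved coverage;
  * for every indel allele seen in both samples, the difference in its
    proportion of coverage between evolved and ancestor exceeds 0.3
    (vacuously true when no allele is shared).

Each decision carries a per-rule audit trail (value, threshold, verdict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VariantRecord",
    "SnpThresholds",
    "IndelThresholds",
    "RuleCheck",
    "FilterDecision",
    "filter_snps",
    "filter_indels",
    "apply_filters",
]

_BASES = ("A", "C", "G", "T", "N")


@dataclass(frozen=True)
class VariantRecord:
    """Per-site allele counts for one sample at one genomic position."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    coverage: int
    base_counts: dict  # base -> count over {A,C,G,T,N}
    indel_counts: dict = field(default_factory=dict)  # allele (e.g. '+A', '-AT') -> count
    sample: str = "evolved"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.ref_base not in _BASES[:4]:
            raise ValueError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")
        bad = set(self.base_counts) - set(_BASES)
        if bad:
            raise ValueError(f"unknown bases in base_counts: {sorted(bad)}")
        if any(c < 0 for c in self.base_counts.values()):
            raise ValueError("negative base count")
        if sum(self.base_counts.values()) > self.coverage:
            raise ValueError("base counts exceed coverage")
        # canonical form: drop zero-count entries so records compare by content
        object.__setattr__(
            self, "base_counts", {b: int(c) for b, c in self.base_counts.items() if c > 0}
        )
        object.__setattr__(
            self, "indel_counts", {a: int(c) for a, c in self.indel_counts.items() if c > 0}
        )

    def count(self, base: str) -> int:
        return int(self.base_counts.get(base, 0))

    @property
    def n_proportion(self) -> float:
        return self.count("N") / self.coverage if self.coverage else 0.0

    @property
    def non_n_reads(self) -> int:
        return sum(self.count(b) for b in "ACGT")

    @property
    def nonref_reads(self) -> int:
        return sum(self.count(b) for b in "ACGT" if b != self.ref_base)

    @property
    def nonref_proportion(self) -> float:
        """Non-reference fraction of non-N base calls (N handled separately)."""
        return self.nonref_reads / self.non_n_reads if self.non_n_reads else 0.0

    @property
    def consensus(self) -> str | None:
        """Most frequent non-N base; None when the site has no base calls."""
        calls = {b: self.count(b) for b in "ACGT"}
        if sum(calls.values()) == 0:
            return None
        return max(sorted(calls), key=calls.get)

    def majority_nonref_fraction(self) -> float:
        nonref = {b: self.count(b) for b in "ACGT" if b != self.ref_base}
        total = sum(nonref.values())
        return max(nonref.values()) / total if total else 0.0


@dataclass(frozen=True)
class SnpThresholds:
    max_n_proportion: float = 0.1
    min_majority_fraction: float = 0.8
    low_nonref: float = 0.1
    high_nonref: float = 0.5


@dataclass(frozen=True)
class IndelThresholds:
    min_coverage: int = 10  # strict: coverage must exceed this
    min_indel_fraction: float = 0.5
    min_top_two_fraction: float = 0.8
    max_ref_fraction: float = 0.5
    min_shared_allele_delta: float = 0.3


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    value: float | str | None
    threshold: str
    passed: bool


@dataclass(frozen=True)
class FilterDecision:
    chrom: str
    pos: int
    kind: str  # 'snp' or 'indel'
    passed: bool
    rules: tuple[RuleCheck, ...]

    @property
    def failed_rules(self) -> tuple[str, ...]:
        return tuple(r.rule for r in self.rules if not r.passed)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "kind": self.kind,
                "rule": [r.rule for r in self.rules],
                "value": [r.value for r in self.rules],
                "threshold": [r.threshold for r in self.rules],
                "passed": [r.passed for r in self.rules],
            }
        )


def _check_pair(anc: VariantRecord, evo: VariantRecord) -> None:
    if (anc.chrom, anc.pos) != (evo.chrom, evo.pos):
        raise ValueError("ancestor and evolved records refer to different positions")
    if anc.ref_base != evo.ref_base:
        raise ValueError("ancestor and evolved records disagree on the reference base")


def filter_snps(
    anc: VariantRecord, evo: VariantRecord, thresholds: SnpThresholds = SnpThresholds()
) -> FilterDecision:
    """Apply the SNP allele-balance rules to one ancestor/evolved site pair."""
    _check_pair(anc, evo)
    t = thresholds
    rules: list[RuleCheck] = []
    if anc.coverage == 0 or evo.coverage == 0:
        rules.append(RuleCheck("coverage", 0, "coverage > 0 in both samples", False))
        return FilterDecision(evo.chrom, evo.pos, "snp", False, tuple(rules))

    n_prop = max(anc.n_proportion, evo.n_proportion)
    rules.append(
        RuleCheck("n_proportion", n_prop, f"< {t.max_n_proportion} (all reads)", n_prop < t.max_n_proportion)
    )

    # evaluate the majority rule in the strain carrying the candidate allele
    carrier = evo if evo.nonref_proportion >= anc.nonref_proportion else anc
    maj = carrier.majority_nonref_fraction()
    rules.append(
        RuleCheck(
            "majority_nonref_fraction", maj,
            f"> {t.min_majority_fraction} of non-reference bases", maj > t.min_majority_fraction,
        )
    )

    p_lo = min(anc.nonref_proportion, evo.nonref_proportion)
    p_hi = max(anc.nonref_proportion, evo.nonref_proportion)
    rules.append(
        RuleCheck(
            "nonref_split", (round(p_lo, 6), round(p_hi, 6)),
            f"< {t.low_nonref} in one strain and > {t.high_nonref} in the other (non-N reads)",
            p_lo < t.low_nonref and p_hi > t.high_nonref,
        )
    )

    consensus_differs = (
        anc.consensus is not None and evo.consensus is not None and anc.consensus != evo.consensus
    )
    rules.append(
        RuleCheck(
            "consensus_differs", f"{anc.consensus}->{evo.consensus}",
            "ancestor and evolved consensus bases differ", consensus_differs,
        )
    )
    return FilterDecision(evo.chrom, evo.pos, "snp", all(r.passed for r in rules), tuple(rules))


def filter_indels(
    anc: VariantRecord, evo: VariantRecord, thresholds: IndelThresholds = IndelThresholds()
) -> FilterDecision:
    """Apply the indel rules to one ancestor/evolved site pair."""
    _check_pair(anc, evo)
    t = thresholds
    rules: list[RuleCheck] = []
    if not evo.indel_counts:
        rules.append(RuleCheck("indel_evidence", 0, ">= 1 indel call in evolved", False))
        return FilterDecision(evo.chrom, evo.pos, "indel", False, tuple(rules))

    cov = evo.coverage
    rules.append(RuleCheck("coverage", cov, f"> {t.min_coverage} (strict)", cov > t.min_coverage))

    indel_total = sum(evo.indel_counts.values())
    indel_frac = indel_total / cov if cov else 0.0
    rules.append(
        RuleCheck("indel_fraction", indel_frac, f"> {t.min_indel_fraction} of coverage",
                  indel_frac > t.min_indel_fraction)
    )

    top_two = sum(sorted(evo.indel_counts.values(), reverse=True)[:2])
    top_two_frac = top_two / indel_total if indel_total else 0.0
    rules.append(
        RuleCheck("top_two_fraction", top_two_frac, f"> {t.min_top_two_fraction} of indel calls",
                  top_two_frac > t.min_top_two_fraction)
    )

    ref_frac = evo.count(evo.ref_base) / cov if cov else 0.0
    rules.append(
        RuleCheck("ref_fraction", ref_frac, f"< {t.max_ref_fraction} of coverage",
                  ref_frac < t.max_ref_fraction)
    )

    shared = set(evo.indel_counts) & set(anc.indel_counts)
    if shared:
        deltas = {
            allele: abs(
                evo.indel_counts[allele] / evo.coverage
                - anc.indel_counts[allele] / anc.coverage
            )
            for allele in shared
            if evo.coverage and anc.coverage
        }
        min_delta = min(deltas.values()) if deltas else 0.0
        ok = bool(deltas) and min_delta > t.min_shared_allele_delta
        rules.append(
            RuleCheck("shared_allele_delta", min_delta,
                      f"> {t.min_shared_allele_delta} for every shared allele", ok)
        )
    else:
        rules.append(
            RuleCheck("shared_allele_delta", None,
                      f"> {t.min_shared_allele_delta} for every shared allele (none shared)", True)
        )
    return FilterDecision(evo.chrom, evo.pos, "indel", all(r.passed for r in rules), tuple(rules))


def _records_by_position(table) -> dict:
    out = {}
    last = None
    for rec in table:
        key = (rec.chrom, rec.pos)
        if last is not None and key < last:
            raise ValueError(f"input not sorted by chrom,pos at {rec.chrom}:{rec.pos}")
        last = key
        out[key] = rec
    return out


def apply_filters(
    anc_table,
    evo_table,
    snp_thresholds: SnpThresholds = SnpThresholds(),
    indel_thresholds: IndelThresholds = IndelThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch filter paired ancestor/evolved variant tables.

    Inputs are iterables of :class:`VariantRecord` sorted by (chrom, pos);
    positions are matched by outer join, and a position present in only one
    table fails as "unpaired".  A site with indel evidence in the evolved
    sample is judged by the indel rules, otherwise by the SNP rules.
    Returns ``(survivors, audit)`` DataFrames; ``audit`` has one row per
    position per rule.
    """
    anc = _records_by_position(anc_table)
    evo = _records_by_position(evo_table)
    decisions: list[FilterDecision] = []
    for key in sorted(set(anc) | set(evo)):
        chrom, pos = key
        if key not in anc or key not in evo:
            decisions.append(
                FilterDecision(
                    chrom, pos, "unpaired", False,
                    (RuleCheck("paired", None, "position present in both tables", False),),
                )
            )
            continue
        if evo[key].indel_counts:
            decisions.append(filter_indels(anc[key], evo[key], indel_thresholds))
        else:
            decisions.append(filter_snps(anc[key], evo[key], snp_thresholds))
    audit = (
        pd.concat([d.audit_frame() for d in decisions], ignore_index=True)
        if decisions
        else pd.DataFrame(columns=["chrom", "pos", "kind", "rule", "value", "threshold", "passed"])
    )
    survivors = pd.DataFrame(
        [
            {"chrom": d.chrom, "pos": d.pos, "kind": d.kind}
            for d in decisions
            if d.passed
        ],
        columns=["chrom", "pos", "kind"],
    )
    return survivors, audit
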