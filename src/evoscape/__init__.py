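"""evoscape: fitness landscapes, epistasis and mutation statistics for
experimental evolution in budding yeast.

The package re-implements, as a reusable library, the quantitative analysis
of a glucose-limited chemostat evolution experiment: selection coefficients
from pairwise competition assays, epistasis between adaptive mutations
(including reciprocal sign epistasis and the two-peaked fitness landscape it
creates), heuristic variant filtering of ancestor/evolved allele-count
tables, copy-number estimation of a tandem amplification from sequencing
depth and qPCR, and neutral-mutation statistics.  A synthetic-data module
generates every input with the statistical structure the analysis assumes.
"""

from importlib import resources

from .competition_fitness import (
    CompetitionTimeSeries,
    RelativeFitness,
    SelectionEstimate,
    ancova_slope_test,
    estimate_selection,
    normalize_selection,
    pool_replicates,
    relative_fitness,
    select_linear_phase,
)
from .epistasis import (
    EpistasisResult,
    additivity_test,
    classify_epistasis,
    epsilon,
    which_locus_flips,
)
from .landscape import (
    FitnessLandscape,
    OptimaReport,
    accessible_paths,
    build_landscape,
    local_optima,
    selection_dynamics,
)
from .mutation_stats import (
    CooccurrenceCounts,
    NeutralModel,
    cooccurrence_count,
    exclusivity_probability,
    expected_neutral_mutations,
    mutation_supply,
    nonsense_capacity,
    poisson_tail,
)
from .variant_filters import (
    FilterDecision,
    IndelThresholds,
    SnpThresholds,
    VariantRecord,
    apply_filters,
    filter_indels,
    filter_snps,
)
from .copy_number import (
    CopyNumberEstimate,
    DepthProfile,
    QpcrMeasurement,
    QpcrResult,
    coverage_ratio,
    min_recombination_events,
    qpcr_copy_number,
    running_median,
    segment_copy_number,
)
from .synthetic_data import (
    LandscapeScenario,
    SCENARIO_DEFAULTS,
    SimulationConfig,
    gen_clone_genotypes,
    gen_competition_series,
    gen_coverage_profiles,
    gen_landscape_scenario,
    gen_variant_tables,
)

__version__ = "0.1.0"


def standin_mth1_cds() -> str:
    """Synthetic stand-in for the MTH1 coding sequence.

    A constructed 434-sense-codon CDS in which exactly 169 codons are one
    nucleotide substitution from a stop codon — the same length and
    nonsense-capacity as the study gene — for exercising the codon scan at
    study scale.  It is NOT the real MTH1 sequence.
    """
    from .io import read_fasta

    path = resources.files("evoscape").joinpath("data/mth1_standin_synthetic.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)
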