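"""Meta-origin analysis of cohesin ChIP-seq, expression and DNA-fiber data.

The package reimplements, as a tested library, the genome-wide analysis
machinery used to study how the cohesin accessory factors Pds5, Wapl and
Brca2 shape cohesin occupancy around early DNA replication origins in
Drosophila BG3 cells: input-normalized sliding-window ChIP enrichment,
meta-origin profile/ratio/test analysis, percentile-threshold binding-region
calling with overlap statistics, regulatory-element enrichment by class,
depletion-contrast RNA expression comparison, and DNA-fiber tract statistics
— all driven by a seeded synthetic-data generator so every stage runs with
ground truth and no external downloads.
"""

from .tracks import CoverageTrack, EnrichmentTrack, n_anchors
from .enrichment import (
    average_replicates,
    compute_enrichment,
    fold_change_track,
    replicate_correlation,
)
from .regions import BindingRegion, OverlapReport, call_regions, intersect_region_sets
from .origins import (
    BinTestResult,
    OriginBinMatrix,
    OriginSet,
    RatioProfile,
    bin_matrix,
    bin_wilcoxon,
    mean_profile,
    ratio_profile,
)
from .elements import (
    ElementEnrichment,
    ElementSet,
    class_depletion_test,
    element_enrichment,
    element_ratio,
    sample_random_elements,
)
from .expression import (
    DepletionContrast,
    ExpressionMatrix,
    OverlapTable,
    active_genes,
    contrast,
    correlate_contrasts,
    overlap_analysis,
)
from .fibers import FiberTable, compare_groups, tract_ratios
from .synthetic import (
    AnnotationBundle,
    ConditionModifiers,
    ExpressionEffectModel,
    FactorOccupancyModel,
    FiberModel,
    SyntheticGenomeSpec,
    calibrate_dispersion,
    expected_coverage,
    fit_decay_scale,
    full_scale_genome_spec,
    simulate_chip,
    simulate_chip_pair,
    simulate_input,
    simulate_expression,
    simulate_fibers,
    simulate_genome,
)

__version__ = "0.1.0"


def bundled_origin_set() -> OriginSet:
    """The bundled 78-record early-origin position list.

    The coordinates are a synthetic stand-in on fly-like chromosome arms
    (see the file docstring header); the record count and format match the
    origin list the meta-origin analysis consumes at full scale.
    """
    from importlib.resources import files

    path = files("metaorigin.data") / "bg3_early_origins_synthetic.bed"
    return OriginSet.from_bed(path, label="early_origins_synthetic")
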