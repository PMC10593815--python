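"""stygodiv: groundwater amphipod biodiversity from eDNA metabarcoding and
citizen-science specimen surveys.

The package covers the full desk-side analysis of a two-method groundwater
survey: decontamination of a replicated ASV read table (index-jump threshold
calibrated on unused index combinations, replicate-consistency filtering,
negative-control verification), identity-threshold taxonomic assignment
calibrated by a barcoding-gap analysis, detection congruence between the two
methods, exact hypergeometric species-ASV co-occurrence screening, and
effort-normalised diversity correlations -- plus a ground-truthed synthetic
data generator emulating the study design, so every stage is testable without
any sequencing data.
"""

from importlib import resources

import pandas as pd

from .io_formats import (
    EffortTable,
    ParseError,
    ReadCountTable,
    ReplicateMeta,
    SequenceRecord,
    SpecimenRecord,
    ValidationError,
    read_count_table,
    read_fasta,
    read_specimen_table,
    write_count_table,
    write_fasta,
    write_specimen_table,
    write_table,
)
from .synthetic import (
    SimulationParams,
    SimulationTruth,
    StudyData,
    generate_occupancy,
    generate_reference_db,
    sample_within_species_queries,
    simulate_citizen_science,
    simulate_edna_counts,
    simulate_study,
)
from .decontam import (
    ControlReport,
    FilterReport,
    JumpThreshold,
    apply_index_jump_filter,
    apply_replicate_filter,
    check_negative_controls,
    decontaminate,
    estimate_index_jump_threshold,
    estimate_per_asv_thresholds,
)
from .taxassign import (
    AlignmentHit,
    Assignment,
    GapReport,
    PlacementRecord,
    align_identity,
    assign_sequences,
    barcoding_gap_analysis,
    classify_placements,
)
from .detection import (
    CongruenceReport,
    DetectionMatrix,
    build_detection_matrix,
    compare_detections,
    effort_normalized_abundance,
)
from .cooccur import (
    CooccurrenceTest,
    CorrelationResult,
    asv_site_matrix,
    cooccur_exact_test,
    pearson_log_correlation,
    richness_summary,
    screen_cooccurrences,
)

from .evaluate import (
    cooccurrence_type_i_rate,
    decontamination_recovery,
    detection_congruence_rates,
    pearson_type_i_rate,
)

__version__ = "0.1.0"


def load_survey_table() -> pd.DataFrame:
    """The published per-species survey summary for the Töss catchment study:
    citizen-science individuals and site counts alongside eDNA metabarcoding
    read and site counts for the six groundwater amphipod species."""
    with resources.files("stygodiv.data").joinpath(
        "toess_amphipod_survey.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t")
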